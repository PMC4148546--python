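"""Survival and classification performance metrics, plus the random-signature null.

Survival mode reports the hazard ratio between median-dichotomized score
groups (with 95% CI), the log-rank p-value at the median cut-point, the Cox
p-value for the continuous score, AUC with its Mann-Whitney p-value, and the
specificity attained at 80% sensitivity.  Binary (treatment-response) mode
reports the odds ratio with Fisher's exact p.  The random-signature null
draws size-matched gene sets uniformly from the gene universe and records the
Cox p-value of each, giving the background against which a selected
signature's association is ranked.

The univariate Cox model is fitted here directly by Newton iteration on the
Efron partial likelihood: the null experiment and the signature-length sweep
fit thousands of models, so a minimal vectorized solver is used, with
``lifelines`` serving as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .expression import (
    EVENT,
    EXCLUDED,
    NO_EVENT,
    DEFAULT_HORIZON_MONTHS,
    SurvivalRecord,
    ValidationError,
    binarize_survival,
)
from .selection import GeneSignature, score_patients

COX_TOL = 1e-7
COX_MAX_ITER = 100
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox proportional-hazards fit."""

    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool


@dataclass
class SurvivalEvaluation:
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    logrank_p: float
    cox_p: float
    auc: float
    auc_p: float
    specificity_at_80_sensitivity: float
    groups: pd.Series  # 1 = high-risk, 0 = low-risk

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("hazard_ratio", self.hazard_ratio, self.hr_ci_low, self.hr_ci_high, np.nan),
            ("logrank_p", self.logrank_p, np.nan, np.nan, self.logrank_p),
            ("cox_p", self.cox_p, np.nan, np.nan, self.cox_p),
            ("auc", self.auc, np.nan, np.nan, self.auc_p),
            ("specificity_at_80_sensitivity",
             self.specificity_at_80_sensitivity, np.nan, np.nan, np.nan),
        ]
        return pd.DataFrame(rows, columns=["metric", "value", "ci_low", "ci_high", "p"])


@dataclass
class BinaryEvaluation:
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    fisher_p: float
    auc: float
    auc_p: float
    specificity_at_80_sensitivity: float
    groups: pd.Series  # 1 = predicted adverse (non-responder), 0 = predicted responder
    or_corrected: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("odds_ratio", self.odds_ratio, self.or_ci_low, self.or_ci_high,
             self.fisher_p),
            ("fisher_p", self.fisher_p, np.nan, np.nan, self.fisher_p),
            ("auc", self.auc, np.nan, np.nan, self.auc_p),
            ("specificity_at_80_sensitivity",
             self.specificity_at_80_sensitivity, np.nan, np.nan, np.nan),
        ]
        return pd.DataFrame(rows, columns=["metric", "value", "ci_low", "ci_high", "p"])


@dataclass
class NullDistribution:
    """Cox p-values of randomly drawn size-matched signatures."""

    p_values: np.ndarray
    n_genes: int
    iterations: int
    seed: int | None
    reference_p: float | None = None

    @property
    def percentile(self) -> float | None:
        """Percent of random signatures the reference signature beats
        (smaller p is better); 100 means it beats them all."""
        if self.reference_p is None:
            return None
        return float(100.0 * np.mean(self.p_values > self.reference_p))

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.p_values < 0.05))


# ---------------------------------------------------------------------------
# Group formation
# ---------------------------------------------------------------------------

def median_dichotomize(scores: pd.Series) -> pd.Series:
    """Split patients at the score median: above -> 1 (high), at/below -> 0."""
    if len(scores) < 2:
        raise ValidationError("need at least 2 patients to dichotomize")
    med = float(scores.median())
    if scores.nunique() == 1:
        raise ValidationError("all scores identical; median split is degenerate")
    return (scores > med).astype(int).rename("risk_group")


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def logrank_test(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank test.

    Returns the chi-square statistic (1 df) and its p-value.  A degenerate
    comparison with zero variance (e.g. no events) returns (0, 1).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2 or min((groups == g).sum() for g in levels) == 0:
        raise ValidationError("log-rank requires two non-empty groups")
    in1 = groups == levels[1]

    observed = 0.0
    expected = 0.0
    variance = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & in1).sum()
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0, 1.0
    chi2 = (observed - expected) ** 2 / variance
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox regression (Efron ties)
# ---------------------------------------------------------------------------

def _cox_prepare(time, event, x):
    """Sort by time ascending and precompute tie structure."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    x = np.asarray(x, dtype=float)
    order = np.argsort(time, kind="mergesort")
    time, event, x = time[order], event[order], x[order]

    # first index of each distinct time (risk set = suffix from that index)
    uniq_t, first_idx = np.unique(time, return_index=True)
    # distinct event times and, per distinct time, the event members
    ev_time_mask = np.array([event[time == t].any() for t in uniq_t])
    return time, event, x, uniq_t[ev_time_mask], first_idx[ev_time_mask]


def cox_univariate(time, event, covariate) -> CoxResult:
    """Fit a univariate Cox proportional-hazards model (Efron ties).

    Newton iteration on the partial log-likelihood; the Wald test gives the
    p-value and the 95% CI for the hazard ratio per unit covariate.  A
    monotone likelihood (perfect separation) or non-convergence is flagged
    via ``converged=False`` rather than reported silently.
    """
    x = np.asarray(covariate, dtype=float)
    event_arr = np.asarray(event, dtype=bool)
    if len(np.unique(x)) < 2:
        raise ValidationError("covariate does not vary")
    if not event_arr.any():
        raise ValidationError("no events observed")

    t_s, e_s, x_s, ev_times, risk_first = _cox_prepare(time, event_arr, x)
    n = len(t_s)

    # per event time: members of the tied event set
    event_slices = []
    d_counts = []
    for t in ev_times:
        members = np.flatnonzero(e_s & (t_s == t))
        event_slices.append(members)
        d_counts.append(len(members))
    d_counts = np.array(d_counts)
    s_sum = np.array([x_s[m].sum() for m in event_slices])  # sum of x over events
    total_events = int(d_counts.sum())

    # flattened Efron correction rows: one row per (event time j, l=0..d_j-1)
    rep = np.repeat(np.arange(len(ev_times)), d_counts)
    frac = np.concatenate([np.arange(d) / d for d in d_counts]) if total_events else np.array([])
    risk_start = risk_first  # suffix index per event time
    ev_members = np.concatenate(event_slices) if event_slices else np.array([], dtype=int)
    ev_groups = np.repeat(np.arange(len(ev_times)), d_counts)

    def suffix_sums(v):
        return np.concatenate([np.cumsum(v[::-1])[::-1], [0.0]])

    def derivatives(beta):
        theta = np.exp(beta * x_s)
        xt = x_s * theta
        x2t = x_s * xt
        S0, S1, S2 = suffix_sums(theta), suffix_sums(xt), suffix_sums(x2t)
        R0, R1, R2 = S0[risk_start], S1[risk_start], S2[risk_start]
        # tied-event sums per event time
        D0 = np.bincount(ev_groups, weights=theta[ev_members], minlength=len(ev_times))
        D1 = np.bincount(ev_groups, weights=xt[ev_members], minlength=len(ev_times))
        D2 = np.bincount(ev_groups, weights=x2t[ev_members], minlength=len(ev_times))
        phi = R0[rep] - frac * D0[rep]
        z1 = R1[rep] - frac * D1[rep]
        z2 = R2[rep] - frac * D2[rep]
        loglik = float(beta * s_sum.sum() - np.log(phi).sum())
        grad = float(s_sum.sum() - (z1 / phi).sum())
        info = float((z2 / phi - (z1 / phi) ** 2).sum())
        return loglik, grad, info

    beta = 0.0
    converged = False
    loglik, grad, info = derivatives(beta)
    for _ in range(COX_MAX_ITER):
        if info <= 0:
            break
        step = grad / info
        # step-halving keeps the likelihood non-decreasing
        new_beta = beta + step
        new_ll, new_grad, new_info = derivatives(new_beta)
        halvings = 0
        while new_ll < loglik and halvings < 30:
            step /= 2
            new_beta = beta + step
            new_ll, new_grad, new_info = derivatives(new_beta)
            halvings += 1
        delta = abs(new_beta - beta)
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if delta < COX_TOL and abs(grad) < COX_TOL * max(1.0, abs(loglik)):
            converged = True
            break

    if info <= 0 or abs(beta) > 50:
        converged = False
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return CoxResult(
        beta=float(beta),
        se=se,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        p=p,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# ROC metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, outcome) -> tuple[float, float]:
    """AUC as the Mann-Whitney concordance probability, with its p-value.

    ``outcome`` is boolean (True = positive class).  Tied score pairs count
    half.  The p-value is two-sided from the normal approximation to the
    Mann-Whitney statistic with tie correction.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    pos, neg = scores[outcome], scores[~outcome]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both outcome classes must be present")
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    auc = float(res.statistic / (len(pos) * len(neg)))
    return auc, float(res.pvalue)


def specificity_at_sensitivity(scores, outcome, sensitivity: float = 0.80) -> float:
    """Largest specificity attainable at the target sensitivity or above.

    Uses the empirical ROC step function with no interpolation; the returned
    specificity belongs to an actual threshold.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if outcome.all() or not outcome.any():
        raise ValidationError("both outcome classes must be present")
    fpr, tpr, _ = roc_curve(outcome.astype(int), scores)
    ok = tpr >= sensitivity
    return float((1 - fpr[ok]).max())


# ---------------------------------------------------------------------------
# 2x2 association
# ---------------------------------------------------------------------------

def odds_ratio_fisher(predicted, observed) -> tuple[float, float, bool]:
    """Odds ratio and two-sided Fisher exact p for predicted vs observed classes.

    Both inputs are boolean arrays.  When a zero cell occurs the OR uses the
    Haldane-Anscombe 0.5 correction and the correction is flagged; the Fisher
    p always uses the uncorrected table.
    """
    predicted = np.asarray(predicted, dtype=bool)
    observed = np.asarray(observed, dtype=bool)
    a = int((predicted & observed).sum())
    b = int((predicted & ~observed).sum())
    c = int((~predicted & observed).sum())
    d = int((~predicted & ~observed).sum())
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValidationError(f"empty margin in 2x2 table [[{a},{b}],[{c},{d}]]")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    oratio = (a_ * d_) / (b_ * c_)
    return float(oratio), float(p), corrected


def _or_ci(a, b, c, d):
    """Woolf logit 95% CI with Haldane correction for zero cells."""
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(np.exp(log_or - _Z95 * se)), float(np.exp(log_or + _Z95 * se))


# ---------------------------------------------------------------------------
# Cohort-level reports
# ---------------------------------------------------------------------------

def evaluate_survival(
    scores: pd.Series,
    records: list[SurvivalRecord],
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
) -> SurvivalEvaluation:
    """Full survival-mode report for one cohort.

    Time-to-event metrics (HR, log-rank, Cox) use every scored patient with
    their full follow-up; classification metrics (AUC, specificity) use only
    patients whose status at the horizon is determined.
    """
    recs = {r.sample_id: r for r in records if r.sample_id in scores.index}
    ids = [s for s in scores.index if s in recs]
    if len(ids) < 2:
        raise ValidationError("fewer than 2 scored patients with survival data")
    sc = scores.loc[ids]
    time = np.array([recs[s].time for s in ids])
    event = np.array([recs[s].event for s in ids])

    groups = median_dichotomize(sc)
    _, lr_p = logrank_test(time, event, groups.to_numpy())
    cox_group = cox_univariate(time, event, groups.to_numpy().astype(float))
    cox_cont = cox_univariate(time, event, sc.to_numpy())

    labels = binarize_survival([recs[s] for s in ids], horizon_months)
    known = labels[labels != EXCLUDED]
    outcome = (known == EVENT).to_numpy()
    auc, auc_p = roc_auc(sc.loc[known.index].to_numpy(), outcome)
    spec = specificity_at_sensitivity(sc.loc[known.index].to_numpy(), outcome)

    return SurvivalEvaluation(
        hazard_ratio=cox_group.hr,
        hr_ci_low=cox_group.ci_low,
        hr_ci_high=cox_group.ci_high,
        logrank_p=lr_p,
        cox_p=cox_cont.p,
        auc=auc,
        auc_p=auc_p,
        specificity_at_80_sensitivity=spec,
        groups=groups,
    )


def evaluate_binary(scores: pd.Series, labels: pd.Series) -> BinaryEvaluation:
    """Binary-mode (treatment response) report for one cohort.

    Scores are median-dichotomized into predicted adverse / favourable
    groups and crossed with the observed classes.
    """
    labels = labels.loc[scores.index]
    keep = labels != EXCLUDED
    sc, lab = scores[keep], labels[keep]
    groups = median_dichotomize(sc)
    observed = (lab == EVENT).to_numpy()
    predicted = groups.to_numpy().astype(bool)
    oratio, fisher_p, corrected = odds_ratio_fisher(predicted, observed)
    a = int((predicted & observed).sum())
    b = int((predicted & ~observed).sum())
    c = int((~predicted & observed).sum())
    d = int((~predicted & ~observed).sum())
    ci_low, ci_high = _or_ci(a, b, c, d)
    auc, auc_p = roc_auc(sc.to_numpy(), observed)
    spec = specificity_at_sensitivity(sc.to_numpy(), observed)
    return BinaryEvaluation(
        odds_ratio=oratio,
        or_ci_low=ci_low,
        or_ci_high=ci_high,
        fisher_p=fisher_p,
        auc=auc,
        auc_p=auc_p,
        specificity_at_80_sensitivity=spec,
        groups=groups,
        or_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Random-signature null
# ---------------------------------------------------------------------------

def random_signature_null(
    z: pd.DataFrame,
    records: list[SurvivalRecord],
    n_genes: int = 12,
    iterations: int = 10_000,
    seed: int | None = None,
    signed: bool = False,
    reference_p: float | None = None,
) -> NullDistribution:
    """Cox p-value distribution of random size-matched signatures.

    Each iteration draws ``n_genes`` genes without replacement, scores every
    patient (all genes in the risk set by default; ``signed=True`` assigns
    each gene a random +/- direction), and fits a univariate Cox model of
    survival on the score.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if n_genes > z.shape[0]:
        raise ValidationError("n_genes exceeds gene count")
    recs = {r.sample_id: r for r in records}
    ids = [s for s in z.columns if s in recs]
    time = np.array([recs[s].time for s in ids])
    event = np.array([recs[s].event for s in ids])
    x = z[ids].to_numpy()

    rng = np.random.default_rng(seed)
    p_values = np.empty(iterations)
    for i in range(iterations):
        idx = rng.choice(z.shape[0], size=n_genes, replace=False)
        if signed:
            signs = rng.choice([1.0, -1.0], size=n_genes)
            score = signs @ x[idx] / n_genes
        else:
            score = x[idx].mean(axis=0)
        p_values[i] = cox_univariate(time, event, score).p
    return NullDistribution(
        p_values=p_values,
        n_genes=n_genes,
        iterations=iterations,
        seed=seed,
        reference_p=reference_p,
    )


def km_curve_points(time, event, groups) -> pd.DataFrame:
    """Kaplan-Meier step-function points per risk group, for TSV export."""
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    groups = np.asarray(groups)
    frames = []
    for g in np.unique(groups):
        kmf = KaplanMeierFitter()
        kmf.fit(time[groups == g], event[groups == g])
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {"group": g, "time": sf.index.to_numpy(),
                 "survival": sf.iloc[:, 0].to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)
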