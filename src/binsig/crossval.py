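"""Leave-one-out cross-validation and signature-length optimization.

Each patient's out-of-fold score comes from a signature selected on the
remaining patients only: the fold re-standardizes and re-bins on its own
n-1 patients, scores and ranks genes against the fold's phenotype labels,
selects the top-n signature, and applies the fold's standardization
parameters to the held-out patient before scoring.  Nothing about the
held-out patient touches fold statistics, so the out-of-fold scores are
leakage-free.

The length sweep fits one criterion per candidate signature length n:
for survival endpoints the p-value from Cox regression of survival on the
continuous out-of-fold scores, for binary endpoints the AUC of the scores
against the class labels.  Because a fold's gene ranking does not depend on
n, the sweep ranks each fold once and slices the top-n prefix per length,
which is exactly equivalent to rerunning the LOOCV per length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import (
    DEFAULT_BIN_LEVEL,
    EVENT,
    EXCLUDED,
    STANDARDIZE_DDOF,
    SurvivalRecord,
    ValidationError,
    bin_expression,
    standardize,
)
from .evaluate import cox_univariate, roc_auc
from .selection import predictive_scores, rank_genes

logger = logging.getLogger("binsig")


@dataclass
class FoldArtifacts:
    """Per-fold products sufficient to score the held-out patient at any n."""

    sample_id: str
    ranked_genes: list[str]
    signs: dict  # gene -> +1/-1 from the fold's predictive-score sign
    n_selectable: int  # genes with nonzero score in this fold
    z_holdout: pd.Series  # held-out expression under the fold's standardization


def _loocv_fold_artifacts(
    m: pd.DataFrame,
    labels: pd.Series,
    level: float = DEFAULT_BIN_LEVEL,
    rebin_per_fold: bool = True,
) -> list[FoldArtifacts]:
    """Run every leave-one-out fold once, independent of signature length.

    ``rebin_per_fold=False`` reproduces a leaky variant that bins on
    whole-cohort statistics; the default re-bins within each fold.
    """
    labels = labels.loc[list(m.columns)]
    classifiable = labels[labels != EXCLUDED].index
    if len(classifiable) < 3:
        raise ValidationError("LOOCV needs at least 3 classifiable patients")

    whole_z = standardize(m)
    whole_bins = bin_expression(whole_z, level=level)

    folds = []
    for sid in classifiable:
        rest = [s for s in m.columns if s != sid]
        sub = m[rest]
        values = sub.to_numpy()
        mean = values.mean(axis=1)
        sd = values.std(axis=1, ddof=STANDARDIZE_DDOF)
        keep = sd > 0
        if not keep.all():
            logger.warning(
                "fold %s: removing %d constant gene(s)", sid, int((~keep).sum())
            )
        genes = sub.index[keep]
        z_fold = pd.DataFrame(
            (values[keep] - mean[keep, None]) / sd[keep, None],
            index=genes, columns=rest,
        )
        if rebin_per_fold:
            bins_fold = bin_expression(z_fold, level=level)
        else:
            bins_fold = whole_bins.loc[genes, rest]
        try:
            table = predictive_scores(bins_fold, z_fold, labels.loc[rest])
        except ValidationError as exc:
            raise ValidationError(
                f"fold holding out patient {sid!r}: {exc}"
            ) from exc
        ranked = rank_genes(table)
        signs = {
            g: (1 if s > 0 else -1)
            for g, s in table["score"].items()
            if s != 0
        }
        # held-out patient standardized with the fold's parameters
        z_holdout = pd.Series(
            (m.loc[genes, sid].to_numpy() - mean[keep]) / sd[keep], index=genes
        )
        folds.append(
            FoldArtifacts(
                sample_id=sid,
                ranked_genes=ranked,
                signs=signs,
                n_selectable=len(signs),
                z_holdout=z_holdout,
            )
        )
    return folds


def _score_fold(fold: FoldArtifacts, n: int) -> float:
    if n < 1:
        raise ValidationError(f"signature length must be >= 1, got {n}")
    if n > fold.n_selectable:
        raise ValidationError(
            f"fold holding out {fold.sample_id!r}: requested {n} genes but only "
            f"{fold.n_selectable} have nonzero score"
        )
    top = fold.ranked_genes[:n]
    signs = np.array([fold.signs[g] for g in top], dtype=float)
    return float(signs @ fold.z_holdout.loc[top].to_numpy() / n)


def loocv_scores(
    m: pd.DataFrame,
    labels: pd.Series,
    n: int,
    level: float = DEFAULT_BIN_LEVEL,
    rebin_per_fold: bool = True,
) -> pd.Series:
    """Out-of-fold signature score for every classifiable patient."""
    folds = _loocv_fold_artifacts(m, labels, level=level,
                                  rebin_per_fold=rebin_per_fold)
    return pd.Series(
        {f.sample_id: _score_fold(f, n) for f in folds}, name="loocv_score"
    )


def sweep_lengths(
    m: pd.DataFrame,
    labels: pd.Series,
    n_range,
    survival_records: list[SurvivalRecord] | None = None,
    mode: str = "survival",
    level: float = DEFAULT_BIN_LEVEL,
    rebin_per_fold: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Criterion value per candidate signature length.

    Returns ``(table, scores)``: a table with one row per length n holding
    the criterion (Cox p of survival on scores, or AUC against class) and
    the number of patients scored, plus the per-patient out-of-fold score
    matrix (patients x lengths).  A Cox fit failure at some n leaves that
    criterion missing with a logged warning.
    """
    n_range = [int(n) for n in n_range]
    if not n_range:
        raise ValidationError("empty signature-length range")
    if mode not in ("survival", "binary"):
        raise ValueError(f"mode must be survival or binary, got {mode!r}")
    if mode == "survival" and survival_records is None:
        raise ValueError("survival mode requires survival_records")

    folds = _loocv_fold_artifacts(m, labels, level=level,
                                  rebin_per_fold=rebin_per_fold)
    ids = [f.sample_id for f in folds]
    score_mat = pd.DataFrame(
        {n: [_score_fold(f, n) for f in folds] for n in n_range}, index=ids
    )

    if mode == "survival":
        recs = {r.sample_id: r for r in survival_records}
        missing = [s for s in ids if s not in recs]
        if missing:
            raise ValidationError(f"patients without survival record: {missing[:5]}")
        time = np.array([recs[s].time for s in ids])
        event = np.array([recs[s].event for s in ids])
    else:
        outcome = (labels.loc[ids] == EVENT).to_numpy()

    rows = []
    for n in n_range:
        sc = score_mat[n].to_numpy()
        try:
            if mode == "survival":
                fit = cox_univariate(time, event, sc)
                crit = fit.p if fit.converged else np.nan
                if not fit.converged:
                    logger.warning("Cox fit did not converge at n=%d", n)
            else:
                crit, _ = roc_auc(sc, outcome)
        except ValidationError as exc:
            logger.warning("criterion failed at n=%d: %s", n, exc)
            crit = np.nan
        rows.append((n, crit, len(ids)))
    table = pd.DataFrame(rows, columns=["n", "criterion", "n_patients_scored"])
    return table, score_mat


def optimal_length(table: pd.DataFrame, mode: str = "survival") -> int:
    """Best signature length: argmin Cox p (survival) or argmax AUC (binary).

    Ties go to the smallest length.
    """
    if table.empty:
        raise ValidationError("empty sweep table")
    ok = table.dropna(subset=["criterion"]).sort_values("n")
    if ok.empty:
        raise ValidationError("no length has a computable criterion")
    if mode == "survival":
        best_val = ok["criterion"].min()
        winners = ok[ok["criterion"] == best_val]
    elif mode == "binary":
        best_val = ok["criterion"].max()
        winners = ok[ok["criterion"] == best_val]
    else:
        raise ValueError(f"mode must be survival or binary, got {mode!r}")
    return int(winners["n"].min())
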