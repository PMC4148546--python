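"""Survival/classification metrics against independent references and oracles."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as lifelines_logrank
from scipy import stats
from sklearn.metrics import roc_auc_score

import binsig as bs
from binsig.expression import ValidationError


def survival_fixture(rng, n=40):
    time = rng.exponential(80, n) + 1
    event = rng.random(n) < 0.7
    groups = rng.integers(0, 2, n)
    # ensure both groups and at least one event
    groups[:2] = [0, 1]
    event[0] = True
    return time, event, groups


class TestMedianDichotomize:
    def test_even_count(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        g = bs.median_dichotomize(s)
        assert g.to_dict() == {"a": 0, "b": 0, "c": 1, "d": 1}

    def test_tie_at_median_goes_low(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert bs.median_dichotomize(s).to_dict() == {"a": 0, "b": 0, "c": 1}

    def test_permutation_invariance(self, rng):
        s = pd.Series(rng.standard_normal(21), index=[f"p{i}" for i in range(21)])
        g1 = bs.median_dichotomize(s)
        g2 = bs.median_dichotomize(s.sample(frac=1, random_state=0))
        pd.testing.assert_series_equal(g1.sort_index(), g2.sort_index())

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValidationError):
            bs.median_dichotomize(pd.Series([2.0, 2.0, 2.0]))


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        time = np.array([5, 10, 15, 5, 10, 15], dtype=float)
        event = np.array([1, 1, 0, 1, 1, 0], dtype=bool)
        groups = np.array([0, 0, 0, 1, 1, 1])
        chi2, p = bs.logrank_test(time, event, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_enumerated_six_patient_instance(self):
        # Event times 2 (group A), 4 (B), 6 (A); censored at 7 (A), 5 (B), 8 (B).
        # O-E for group A per event time: t=2: 1 - 3/6; t=4: 0 - 2/5; t=6: 1 - 2/3
        # -> O-E = 13/30; V = 1/4 + 6/25 + 2/9 = 641/900
        # chi2 = (13/30)^2 / (641/900) = 169/641
        time = np.array([2, 7, 6, 4, 5, 8], dtype=float)
        event = np.array([1, 0, 1, 1, 0, 0], dtype=bool)
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        chi2, p = bs.logrank_test(time, event, groups)
        assert chi2 == pytest.approx(169 / 641, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(169 / 641, 1), abs=1e-12)

    def test_matches_lifelines_on_random_fixtures(self, rng):
        for _ in range(20):
            time, event, groups = survival_fixture(rng)
            chi2, p = bs.logrank_test(time, event, groups)
            ref = lifelines_logrank(
                time[groups == 0], time[groups == 1],
                event[groups == 0], event[groups == 1],
            )
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-6)
            assert p == pytest.approx(ref.p_value, abs=1e-6)

    def test_no_events_is_degenerate(self):
        chi2, p = bs.logrank_test([3, 4, 5, 6], [0, 0, 0, 0], [0, 0, 1, 1])
        assert (chi2, p) == (0.0, 1.0)


class TestCoxUnivariate:
    def test_matches_lifelines_on_random_fixtures(self, rng):
        for i in range(20):
            time, event, _ = survival_fixture(rng, n=60)
            x = rng.standard_normal(60) + 0.3 * event
            fit = bs.cox_univariate(time, event, x)
            assert fit.converged
            df = pd.DataFrame({"t": time, "e": event.astype(int), "x": x})
            # tighten lifelines' stopping rule so both solvers sit at the optimum
            ref = CoxPHFitter().fit(
                df, "t", "e", fit_options={"precision": 1e-12, "max_steps": 500}
            )
            assert fit.beta == pytest.approx(float(ref.params_.iloc[0]), abs=1e-6)
            assert fit.se == pytest.approx(float(ref.standard_errors_.iloc[0]),
                                           abs=1e-6)
            assert fit.p == pytest.approx(float(ref.summary["p"].iloc[0]),
                                          abs=1e-6)

    def test_handles_heavily_tied_times_like_lifelines(self, rng):
        # integer-rounded times force Efron tie handling
        time = np.ceil(rng.exponential(6, 80))
        event = rng.random(80) < 0.8
        event[0] = True
        x = rng.standard_normal(80)
        fit = bs.cox_univariate(time, event, x)
        df = pd.DataFrame({"t": time, "e": event.astype(int), "x": x})
        ref = CoxPHFitter().fit(
            df, "t", "e", fit_options={"precision": 1e-12, "max_steps": 500}
        )
        assert fit.beta == pytest.approx(float(ref.params_.iloc[0]), abs=1e-6)

    def test_covariate_rescaling_rescales_beta(self, rng):
        time, event, _ = survival_fixture(rng, n=50)
        x = rng.standard_normal(50)
        a = bs.cox_univariate(time, event, x)
        b = bs.cox_univariate(time, event, 4.0 * x)
        assert b.beta == pytest.approx(a.beta / 4.0, rel=1e-5)

    def test_null_covariate_type_one_error(self):
        # independent covariate: HR ~ 1 and p < .05 about 5% of the time
        hits, n_sim = 0, 300
        betas = []
        for seed in range(n_sim):
            r = np.random.default_rng(seed)
            time = r.exponential(50, 120)
            event = r.random(120) < 0.7
            event[0] = True
            x = r.standard_normal(120)
            fit = bs.cox_univariate(time, event, x)
            betas.append(fit.beta)
            hits += fit.p < 0.05
        assert abs(np.mean(betas)) < 0.03
        # binomial(300, .05): allow a generous band
        assert 0.02 <= hits / n_sim <= 0.09

    def test_group_indicator_agrees_with_logrank(self, rng):
        time, event, groups = survival_fixture(rng, n=200)
        fit = bs.cox_univariate(time, event, groups.astype(float))
        _, lr_p = bs.logrank_test(time, event, groups)
        # score/Wald tests agree asymptotically, not exactly
        assert np.log10(fit.p) == pytest.approx(np.log10(lr_p), abs=0.5)

    def test_relabeling_inverts_hazard_ratio(self, rng):
        time, event, groups = survival_fixture(rng, n=80)
        a = bs.cox_univariate(time, event, groups.astype(float))
        b = bs.cox_univariate(time, event, 1.0 - groups)
        assert a.hr == pytest.approx(1.0 / b.hr, rel=1e-5)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            bs.cox_univariate([1, 2, 3], [1, 1, 0], [2.0, 2.0, 2.0])

    def test_perfect_separation_flagged(self):
        # covariate orders patients exactly by event time: monotone likelihood
        time = np.arange(1.0, 31.0)
        event = np.ones(30, dtype=bool)
        x = -np.arange(30.0)
        fit = bs.cox_univariate(time, event, x)
        assert not fit.converged


def mannwhitney_p_oracle(pos, neg):
    """Two-sided normal approximation with tie correction and continuity."""
    n1, n2 = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    ranks = stats.rankdata(allv)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    _, counts = np.unique(allv, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12 * (n + 1 - tie_term))
    z = (abs(u - mu) - 0.5) / sigma
    return 2 * stats.norm.sf(z)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = bs.roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert auc == 1.0

    def test_all_tied_scores(self):
        auc, p = bs.roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert auc == 0.5

    def test_pair_counting_oracle(self, rng):
        for _ in range(20):
            scores = rng.choice(np.linspace(0, 1, 12), size=30)  # forces ties
            outcome = rng.integers(0, 2, 30).astype(bool)
            outcome[:2] = [True, False]
            auc, p = bs.roc_auc(scores, outcome)
            pos, neg = scores[outcome], scores[~outcome]
            pairs = (pos[:, None] > neg).sum() + 0.5 * (pos[:, None] == neg).sum()
            assert auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(outcome, scores), abs=1e-9)
            assert p == pytest.approx(mannwhitney_p_oracle(pos, neg), abs=1e-9)

    def test_score_negation_complements_auc(self, rng):
        scores = rng.standard_normal(40)  # tie-free
        outcome = rng.integers(0, 2, 40).astype(bool)
        outcome[:2] = [True, False]
        a, _ = bs.roc_auc(scores, outcome)
        b, _ = bs.roc_auc(-scores, outcome)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            bs.roc_auc([1, 2, 3], [1, 1, 1])


class TestSpecificityAtSensitivity:
    def test_perfect_classifier(self):
        spec = bs.specificity_at_sensitivity([1, 2, 9, 10], [0, 0, 1, 1])
        assert spec == 1.0

    def test_exhaustive_threshold_scan_oracle(self, rng):
        for _ in range(20):
            scores = rng.choice(np.linspace(0, 1, 15), size=40)
            outcome = rng.integers(0, 2, 40).astype(bool)
            outcome[:2] = [True, False]
            got = bs.specificity_at_sensitivity(scores, outcome, 0.80)
            best = 0.0
            for thr in np.unique(scores):
                pred = scores >= thr
                sens = (pred & outcome).sum() / outcome.sum()
                spec = (~pred & ~outcome).sum() / (~outcome).sum()
                if sens >= 0.80:
                    best = max(best, spec)
            assert got == pytest.approx(best, abs=1e-12)

    def test_uninformative_scores_approach_complement(self, rng):
        # with no signal, achieving 80% sensitivity costs ~80% of controls
        scores = rng.standard_normal(4000)
        outcome = rng.integers(0, 2, 4000).astype(bool)
        spec = bs.specificity_at_sensitivity(scores, outcome, 0.80)
        assert spec == pytest.approx(0.20, abs=0.04)


def fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric tails over fixed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    kmin, kmax = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: stats.hypergeom.pmf(k, n, c1, r1) for k in range(kmin, kmax + 1)}
    p_obs = pmf[a]
    return sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-9))


class TestOddsRatioFisher:
    def test_analytic_table(self):
        pred = [1] * 10 + [0] * 10
        obs = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        oratio, p, corrected = bs.odds_ratio_fisher(pred, obs)
        assert oratio == pytest.approx(16.0)
        assert not corrected

    def test_symmetric_table(self):
        pred = [1] * 10 + [0] * 10
        obs = [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5
        oratio, p, _ = bs.odds_ratio_fisher(pred, obs)
        assert oratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_cell_uses_haldane_correction(self):
        pred = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        obs = np.array([1, 1, 1, 0, 0, 1], dtype=bool)
        oratio, _, corrected = bs.odds_ratio_fisher(pred, obs)
        assert corrected
        assert oratio == pytest.approx((3.5 * 2.5) / (0.5 * 1.5))

    def test_fisher_p_matches_enumeration(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 2, 25).astype(bool)
            obs = rng.integers(0, 2, 25).astype(bool)
            pred[:2], obs[:2] = [True, False], [True, False]
            pred[2:4], obs[2:4] = [False, True], [True, False]
            a = int((pred & obs).sum()); b = int((pred & ~obs).sum())
            c = int((~pred & obs).sum()); d = int((~pred & ~obs).sum())
            _, p, _ = bs.odds_ratio_fisher(pred, obs)
            assert p == pytest.approx(fisher_p_enumeration(a, b, c, d), abs=1e-9)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValidationError):
            bs.odds_ratio_fisher([1, 1, 1], [1, 0, 1])


@pytest.fixture(scope="module")
def null_cohort():
    cfg = bs.SimulationConfig(n_genes=120, n_samples=60, effect_size=0.0, seed=42)
    m, records, _ = bs.simulate_survival_cohort(cfg)
    return bs.standardize(m), records


class TestRandomSignatureNull:

    def test_deterministic_under_seed(self, null_cohort):
        z, records = null_cohort
        a = bs.random_signature_null(z, records, iterations=50, seed=1)
        b = bs.random_signature_null(z, records, iterations=50, seed=1)
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_reference_beating_all_has_percentile_100(self, null_cohort):
        z, records = null_cohort
        null = bs.random_signature_null(z, records, iterations=50, seed=2,
                                        reference_p=0.0)
        assert null.percentile == 100.0

    def test_signed_mode_differs(self, null_cohort):
        z, records = null_cohort
        a = bs.random_signature_null(z, records, iterations=20, seed=3)
        b = bs.random_signature_null(z, records, iterations=20, seed=3,
                                     signed=True)
        assert not np.allclose(a.p_values, b.p_values)

    def test_iteration_and_size_validation(self, null_cohort):
        z, records = null_cohort
        with pytest.raises(ValueError):
            bs.random_signature_null(z, records, iterations=0)
        with pytest.raises(ValidationError):
            bs.random_signature_null(z, records, n_genes=10_000)


class TestCohortReports:
    def test_survival_report_invariants(self, small_cohort):
        m, records, labels, _ = small_cohort
        z = bs.standardize(m)
        table = bs.predictive_scores(bs.bin_expression(z), z, labels)
        sig = bs.select_signature(table, 4)
        rep = bs.evaluate_survival(bs.score_patients(sig, z), records)
        assert rep.hazard_ratio > 0
        assert 0 <= rep.auc <= 1
        assert 0 <= rep.specificity_at_80_sensitivity <= 1
        for p in (rep.logrank_p, rep.cox_p, rep.auc_p):
            assert 0 <= p <= 1
        assert set(rep.groups.unique()) <= {0, 1}
        frame = rep.to_frame()
        assert set(frame["metric"]) >= {"hazard_ratio", "logrank_p", "auc"}

    def test_binary_report_invariants(self):
        cfg = bs.SimulationConfig(n_genes=50, n_samples=40, n_informative=4,
                                  effect_size=1.0, seed=8, endpoint_mode="binary")
        m, records, _ = bs.simulate_response_cohort(cfg)
        labels = bs.binarize_response(records)
        z = bs.standardize(m)
        table = bs.predictive_scores(bs.bin_expression(z), z, labels)
        sig = bs.select_signature(table, 4)
        rep = bs.evaluate_binary(bs.score_patients(sig, z), labels)
        assert rep.odds_ratio >= 0
        assert 0 <= rep.fisher_p <= 1
        assert 0 <= rep.auc <= 1
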