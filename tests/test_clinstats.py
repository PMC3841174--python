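import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coosig import clinstats
from coosig.clinstats import (
    cox_ph,
    cox_score_test_binary,
    fisher_exact,
    kaplan_meier_curve,
    logrank_test,
    mann_whitney_tiecorrected,
    permutation_signature_null,
    proportional_odds_assoc,
    welch_t,
)
from coosig.simulate import CohortSimConfig, simulate_tumor_cohort


class TestMannWhitney:
    # the three printed two-group binary count tables are this module's
    # exact acceptance surface (see also tests/test_acceptance.py)
    def test_ascites_counts(self):
        rep = mann_whitney_tiecorrected([0] * 13, [0, 0, 0, 1, 1, 1])
        assert round(rep.p_value, 3) == 0.007

    def test_lung_metastasis_counts(self):
        rep = mann_whitney_tiecorrected([1, 1, 1, 1, 0, 0], [1, 0, 0, 0, 0, 0, 0, 0])
        assert round(rep.p_value, 2) == 0.04

    def test_tumor_formation_counts(self):
        rep = mann_whitney_tiecorrected([1] * 13 + [0] * 2, [1] * 6 + [0] * 3)
        assert round(rep.p_value, 2) == 0.25

    def test_hand_derived_z_for_ascites(self):
        # U = 58.5 for group B, var = (78/12) * (20 - 4104/342) = 52
        rep = mann_whitney_tiecorrected([0] * 13, [0, 0, 0, 1, 1, 1])
        assert abs(rep.extras["z"]) == pytest.approx(19.5 / np.sqrt(52.0), abs=1e-12)

    def test_identical_groups(self):
        rep = mann_whitney_tiecorrected([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.statistic == pytest.approx(4.5)
        assert rep.p_value == pytest.approx(1.0)

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning):
            rep = mann_whitney_tiecorrected([5.0] * 4, [5.0] * 3)
        assert rep.p_value == 1.0

    def test_matches_scipy_asymptotic_no_continuity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, size=rng.integers(3, 15)).astype(float)
            b = rng.integers(0, 4, size=rng.integers(3, 15)).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            rep = mann_whitney_tiecorrected(a, b)
            ref = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=False
            )
            assert rep.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_label_swap_invariance(self):
        a, b = [1.0, 2.0, 5.0], [0.0, 3.0, 3.0, 7.0]
        assert mann_whitney_tiecorrected(a, b).p_value == pytest.approx(
            mann_whitney_tiecorrected(b, a).p_value, abs=1e-12
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_tiecorrected([], [1.0])


class TestFisherExact:
    def test_diagonal_5x5(self):
        # full hypergeometric enumeration: p = 2/C(10,5) = 2/252
        rep = fisher_exact([[5, 0], [0, 5]])
        assert rep.p_value == pytest.approx(2 / 252, abs=1e-12)

    def test_flat_table(self):
        assert fisher_exact([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_2x3_monte_carlo_matches_enumeration(self):
        table = [[4, 1, 2], [1, 5, 3]]
        exact = fisher_exact(table)
        assert exact.extras["method"] == "enumeration"
        n_iter = 40_000
        mc = fisher_exact(table, mc_iterations=n_iter, seed=1, force_monte_carlo=True)
        assert mc.extras["method"] == "monte_carlo"
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / n_iter)
        assert abs(mc.p_value - exact.p_value) < 2 * se + 2 / n_iter

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [1, 2]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [1, 1]])


class TestProportionalOdds:
    def test_null_uniform_p(self):
        pvals = []
        for seed in range(120):
            rng = np.random.default_rng(seed)
            outcome = rng.integers(0, 3, size=500)
            group = rng.integers(0, 2, size=500)
            pvals.append(proportional_odds_assoc(outcome, group).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_matches_grid_search_oracle(self):
        # tiny 3-level outcome; dense grid over (cut1, cut2, beta)
        outcome = np.array([0] * 8 + [1] * 5 + [2] * 3 + [0] * 2 + [1] * 6 + [2] * 9)
        group = np.array([0] * 16 + [1] * 17)
        rep = proportional_odds_assoc(outcome, group)
        llf_full = rep.statistic / 2.0 + _intercept_only_llf(outcome)

        best = -np.inf
        cuts1 = np.linspace(-3, 3, 61)
        deltas = np.linspace(0.05, 4, 40)
        betas = np.linspace(-4, 4, 81)
        x = group.astype(float)
        for c1 in cuts1:
            for d in deltas:
                c2 = c1 + d
                for b in betas:
                    eta = x * b
                    p0 = _expit(c1 - eta)
                    p1 = _expit(c2 - eta) - p0
                    p2 = 1 - _expit(c2 - eta)
                    probs = np.stack([p0, p1, p2])[outcome, np.arange(len(outcome))]
                    if np.any(probs <= 0):
                        continue
                    best = max(best, np.log(probs).sum())
        assert llf_full >= best - 1e-4

    def test_null_construction_log_odds_near_zero(self):
        # outcome levels equally likely in both classes by construction
        outcome = np.tile([0, 1, 2], 40)
        group = np.repeat([0, 1], 60)
        rep = proportional_odds_assoc(outcome, group)
        assert abs(rep.extras["log_odds"]) < 1e-4
        assert rep.p_value > 0.99

    def test_requires_two_levels(self):
        with pytest.raises(ValueError):
            proportional_odds_assoc([1, 1, 1, 1], [0, 1, 0, 1])


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


def _intercept_only_llf(outcome):
    counts = np.bincount(outcome)
    counts = counts[counts > 0]
    return float(np.sum(counts * np.log(counts / counts.sum())))


class TestWelch:
    def test_identical_groups(self):
        rep = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_hand_formula(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 2, 18)
        rep = welch_t(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        assert rep.statistic == pytest.approx(t, abs=1e-12)
        assert rep.df == pytest.approx(df, abs=1e-9)
        assert rep.p_value == pytest.approx(2 * stats.t.sf(abs(t), df), abs=1e-12)

    def test_equal_variance_equal_n_df_near_pooled(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 40)
        rep = welch_t(a, b)
        assert abs(rep.df - 78) < 5

    def test_power_at_unit_shift(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(800 + seed)
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            hits += welch_t(a, b).p_value < 0.05
        assert hits / 50 > 0.99

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestLogrank:
    def test_identical_experience(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 1, 1, 1, 1]
        groups = [0, 0, 0, 1, 1, 1]
        rep = logrank_test(times, events, groups)
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)
        assert rep.p_value == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # A: deaths at 1,2,3; B: deaths at 4,5,6
        # O-E for B: t=1: 0-3/6; t=2: 0-3/5; t=3: 0-3/4
        # t=4: 1-3/3=0; t=5: 1-2/2=0; t=6: 1-1/1=0
        # V: t=1: (3*3)/(6*6) * (6-1)/(6-1)... hypergeometric var per time
        times = [1, 2, 3, 4, 5, 6]
        events = [1] * 6
        groups = [0, 0, 0, 1, 1, 1]
        o_minus_e = -(3 / 6 + 3 / 5 + 3 / 4)
        var = (3 * 3) / 36 + (2 * 3) / 25 + (1 * 3) / 16
        rep = logrank_test(times, events, groups)
        assert rep.statistic == pytest.approx(o_minus_e**2 / var, abs=1e-10)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(9)
        times = rng.exponential(10, 80)
        events = rng.integers(0, 2, 80)
        groups = rng.integers(0, 2, 80)
        events[0] = 1
        rep = logrank_test(times, events, groups)
        ref = ll_logrank(
            times[groups == 0], times[groups == 1],
            events[groups == 0], events[groups == 1],
        )
        assert rep.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert rep.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_power_under_hazard_ratio_3(self):
        significant = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(900 + seed)
            t0 = rng.exponential(10.0, 150)
            t1 = rng.exponential(10.0 / 3.0, 150)
            times = np.concatenate([t0, t1])
            events = np.ones(300, dtype=int)
            groups = np.repeat([0, 1], 150)
            if logrank_test(times, events, groups).p_value < 0.001:
                significant += 1
        assert significant / n_seeds >= 0.95

    def test_no_events_warns(self):
        with pytest.warns(UserWarning):
            rep = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert rep.p_value == 1.0


class TestCox:
    def test_score_test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(10)
        times = rng.exponential(5, 60)
        assert len(np.unique(times)) == 60  # no ties
        events = np.ones(60, dtype=int)
        group = rng.integers(0, 2, 60)
        score = cox_score_test_binary(times, events, group)
        lr = logrank_test(times, events, group)
        assert score.statistic == pytest.approx(lr.statistic, abs=1e-6)

    def test_null_covariate_hr_near_one(self):
        hrs = []
        for seed in range(15):
            rng = np.random.default_rng(1000 + seed)
            times = rng.exponential(5, 200)
            events = np.ones(200, dtype=int)
            covs = pd.DataFrame({"x": rng.integers(0, 2, 200).astype(float)})
            hrs.append(cox_ph(times, events, covs)["hazard_ratio"].iloc[0])
        assert abs(np.log(hrs).mean()) < 0.1

    def test_hr_recovery(self):
        within = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1100 + seed)
            x = rng.integers(0, 2, 400).astype(float)
            rates = 0.1 * np.exp(np.log(2.0) * x)
            times = rng.exponential(1.0 / rates)
            events = np.ones(400, dtype=int)
            hr = cox_ph(times, events, pd.DataFrame({"x": x}))["hazard_ratio"].iloc[0]
            within += 1.7 <= hr <= 2.3
        assert within / n_seeds >= 0.9

    def test_requires_events(self):
        with pytest.raises(ValueError):
            cox_ph([1.0, 2.0], [0, 0], pd.DataFrame({"x": [0.0, 1.0]}))


class TestKaplanMeier:
    def test_simple_curve(self):
        km = kaplan_meier_curve([1, 2, 3, 4], [1, 1, 0, 1])
        # S(1)=3/4, S(2)=3/4*2/3=1/2, S(4)=1/2*0 = 0
        assert list(km["survival"]) == pytest.approx([1.0, 0.75, 0.5, 0.0])
        assert list(km["n_at_risk"]) == [4, 4, 3, 1]


class TestPermutationNull:
    def test_zero_permutations_empty(self, tumor_cohort):
        matrix, clinical, _ = tumor_cohort
        result = permutation_signature_null(matrix, clinical, 5, 0, seed=0)
        assert result.p_values.empty
        assert result.fraction_significant == {}

    def test_deterministic_under_seed(self, tumor_cohort):
        matrix, clinical, _ = tumor_cohort
        r1 = permutation_signature_null(matrix, clinical, 5, 4, seed=3)
        r2 = permutation_signature_null(matrix, clinical, 5, 4, seed=3)
        pd.testing.assert_frame_equal(r1.p_values, r2.p_values)

    def test_calibration_with_independent_clinical(self, signature10):
        # expression carries class structure but the clinical covariates are
        # re-drawn independently -> each association's false-positive rate
        # should sit within the binomial CI of alpha
        config = CohortSimConfig(
            n_tumors=200, n_extra_probesets=100, class_mean_shift=1.0, seed=55
        )
        matrix, clinical, _ = simulate_tumor_cohort(config, signature10)
        rng = np.random.default_rng(99)
        df = clinical.table.copy()
        df["grade"] = rng.integers(1, 4, len(df))
        df["stage"] = rng.integers(1, 5, len(df))
        df["subtype"] = rng.choice(["serous", "endometrioid", "mucinous"], len(df))
        from coosig.datatypes import ClinicalTable

        shuffled = ClinicalTable(df)
        n_perm = 150
        result = permutation_signature_null(
            matrix, shuffled, 5, n_perm, alpha=0.05, seed=7
        )
        assert result.n_failures <= n_perm * 0.05
        half_width = 3 * np.sqrt(0.05 * 0.95 / n_perm)
        for name, frac in result.fraction_significant.items():
            assert frac <= 0.05 + half_width, (name, frac)
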