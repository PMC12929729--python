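"""Median split, Kaplan-Meier, log-rank, Cox, enrichment: closed-form and
hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

from spotmark import bulk, synthetic
from spotmark.stats import bh_adjust


class TestMedianSplit:
    def test_even_count_splits_in_half(self):
        high = bulk.median_split([1, 2, 3, 4])
        assert high.tolist() == [False, False, True, True]

    def test_value_equal_to_median_goes_low(self):
        high = bulk.median_split([1, 2, 3])
        assert high.tolist() == [False, False, True]

    def test_invariant_to_monotone_transform(self):
        v = np.array([0.5, 1.5, 2.5, 9.0, 3.0])
        assert np.array_equal(bulk.median_split(v), bulk.median_split(np.exp(v)))

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            bulk.median_split([2.0, 2.0, 2.0])


class TestKaplanMeier:
    def test_no_events_means_flat_survival(self):
        km = bulk.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_two_subjects_closed_form(self):
        km = bulk.km_estimate([1.0, 2.0], [1, 1]).set_index("time")
        assert km.loc[1.0, "survival"] == pytest.approx(0.5)
        assert km.loc[2.0, "survival"] == pytest.approx(0.0)

    def test_matches_hand_computed_product_limit_table(self):
        """times 1,2+,3,4,4,5+ (+ censored): S(1)=5/6, S(3)=5/6*3/4,
        S(4)=5/6*3/4*1/3."""
        times = [1, 2, 3, 4, 4, 5]
        events = [1, 0, 1, 1, 1, 0]
        km = bulk.km_estimate(times, events).set_index("time")
        assert km.loc[1, "survival"] == pytest.approx(5 / 6, abs=1e-12)
        assert km.loc[3, "survival"] == pytest.approx(5 / 6 * 3 / 4, abs=1e-12)
        assert km.loc[4, "survival"] == pytest.approx(5 / 6 * 3 / 4 * 1 / 3, abs=1e-12)
        assert km.loc[4, "n_at_risk"] == 3

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50).round(2) + 0.01
        km = bulk.km_estimate(t, np.ones(50, int)).set_index("time")
        for ti in np.unique(t):
            assert km.loc[ti, "survival"] == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_curve_monotone_non_increasing_from_one(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 80) + 0.01
        e = rng.binomial(1, 0.6, 80)
        km = bulk.km_estimate(t, e)
        s = km["survival"].to_numpy()
        assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bulk.km_estimate([], [])


def logrank_reference(ta, ea, tb, eb):
    """Observed-minus-expected log-rank chi-square, computed directly."""
    ta, ea, tb, eb = map(np.asarray, (ta, ea, tb, eb))
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O_E = 0.0
    V = 0.0
    for t in times:
        n1 = (ta >= t).sum()
        n2 = (tb >= t).sum()
        d1 = ((ta == t) & (ea == 1)).sum()
        d2 = ((tb == t) & (eb == 1)).sum()
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        O_E += d1 - d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return O_E**2 / V


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 1, 0]
        stat, p = bulk.logrank(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_matches_hand_computed_six_subject_toy(self):
        ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
        tb, eb = [2.0, 4.0, 6.0], [1, 1, 1]
        stat, _ = bulk.logrank(ta, ea, tb, eb)
        assert stat == pytest.approx(logrank_reference(ta, ea, tb, eb), abs=1e-10)

    def test_invariant_to_group_swap(self):
        rng = np.random.default_rng(3)
        ta = rng.exponential(5, 40) + 0.01
        tb = rng.exponential(10, 35) + 0.01
        ea = rng.binomial(1, 0.7, 40)
        eb = rng.binomial(1, 0.7, 35)
        s1, p1 = bulk.logrank(ta, ea, tb, eb)
        s2, p2 = bulk.logrank(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_strong_separation_is_significant(self):
        cohort, _ = synthetic.simulate_bulk_cohort(
            400, beta=np.log(5.0), covariate_spec={}, censor_rate=0.1, seed=5)
        high = bulk.median_split(cohort.marker("SLC2A1").to_numpy())
        clin = cohort.clinical
        t, e = clin["time"].to_numpy(), clin["event"].to_numpy()
        _, p = bulk.logrank(t[high], e[high], t[~high], e[~high])
        assert p < 0.001

    def test_no_events_returns_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="no events"):
            stat, p = bulk.logrank([1.0, 2.0], [0, 0], [1.5], [0])
        assert p == 1.0


class TestCox:
    def test_null_covariate_ci_contains_one(self):
        cohort, _ = synthetic.simulate_bulk_cohort(2000, beta=0.0, seed=11)
        table = bulk.cox_ph(cohort, "SLC2A1").set_index("term")
        row = table.loc["marker_high"]
        assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_planted_log2_effect_recovered(self):
        cohort, _ = synthetic.simulate_bulk_cohort(2000, beta=np.log(2.0), seed=12)
        table = bulk.cox_ph(cohort, "SLC2A1").set_index("term")
        assert 1.7 <= table.loc["marker_high", "HR"] <= 2.35

    def test_score_test_equals_logrank_for_single_binary_covariate(self):
        """At beta=0 the Cox partial-likelihood score test for one binary
        covariate is the log-rank statistic; with no ties the fitted model's
        log-rank equivalence holds to numerical accuracy."""
        rng = np.random.default_rng(13)
        n = 120
        g = rng.binomial(1, 0.5, n).astype(bool)
        t = rng.exponential(np.where(g, 5.0, 10.0)) + rng.uniform(0, 1e-6, n)
        e = np.ones(n, int)
        stat, _ = bulk.logrank(t[g], e[g], t[~g], e[~g])
        # score statistic U(0)^2 / I(0) computed directly from the partial
        # likelihood of the binary covariate
        order = np.argsort(t)
        ts, gs = t[order], g[order].astype(float)
        U = 0.0
        I = 0.0
        for i in range(n):
            at_risk = gs[i:]
            p = at_risk.mean()
            U += gs[i] - p
            I += p * (1 - p)
        assert stat == pytest.approx(U**2 / I, rel=1e-6)

    def test_ci_contains_hr_and_hr_positive(self):
        cohort, _ = synthetic.simulate_bulk_cohort(500, beta=0.5, seed=14)
        table = bulk.cox_ph(cohort, "SLC2A1")
        assert (table["HR"] > 0).all()
        assert ((table["ci_low"] <= table["HR"]) & (table["HR"] <= table["ci_high"])).all()

    def test_too_few_events_rejected(self):
        cohort, _ = synthetic.simulate_bulk_cohort(40, beta=0.0, censor_rate=0.0, seed=15)
        clin = cohort.clinical.copy()
        clin.loc[:, "event"] = 0
        clin.iloc[:2, clin.columns.get_loc("event")] = 1
        from spotmark.containers import BulkCohort

        crippled = BulkCohort(expression=cohort.expression, clinical=clin)
        with pytest.raises(ValueError, match="events"):
            bulk.cox_ph(crippled, "SLC2A1")


class TestEnrichmentAndBH:
    def test_balanced_table_gives_or_one_p_one(self):
        hi = pd.DataFrame({"TP53": [1] * 5 + [0] * 5})
        lo = pd.DataFrame({"TP53": [1] * 5 + [0] * 5})
        out = bulk.fisher_enrichment(hi, lo)
        assert out.loc["TP53", "p"] == pytest.approx(1.0)
        assert out.loc["TP53", "odds_ratio"] == pytest.approx(1.0, abs=0.05)

    def test_bh_stepup_formula(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_bh_monotone_and_capped(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0).all() and (q >= p - 1e-12).all()

    def test_matches_hypergeometric_enumeration_on_random_tables(self):
        from scipy import stats

        rng = np.random.default_rng(9)
        for _ in range(25):
            a, b, c, d = rng.integers(1, 8, 4)
            hi = pd.DataFrame({"G": [1] * a + [0] * b})
            lo = pd.DataFrame({"G": [1] * c + [0] * d})
            out = bulk.fisher_enrichment(hi, lo)
            n, K, nn = a + b + c + d, a + c, a + b
            support = range(max(0, nn - (n - K)), min(K, nn) + 1)
            pmf = {k: stats.hypergeom.pmf(k, n, K, nn) for k in support}
            p_ref = sum(v for v in pmf.values() if v <= pmf[a] * (1 + 1e-9))
            assert out.loc["G", "p"] == pytest.approx(p_ref, abs=1e-12)


class TestSurvivalAnalysis:
    def test_overall_flow_produces_consistent_result(self):
        cohort, _ = synthetic.simulate_bulk_cohort(600, beta=np.log(2.64), seed=20)
        res = bulk.survival_analysis(cohort, "SLC2A1")
        assert res.logrank_p < 0.01
        hr = res.cox_table.set_index("term").loc["marker_high", "HR"]
        assert hr > 1.0
        assert res.km_high["survival"].iloc[-1] <= res.km_low["survival"].iloc[-1]

    def test_subgroup_filter_after_full_cohort_split(self):
        cohort, _ = synthetic.simulate_bulk_cohort(600, beta=0.5, seed=21)
        stage12 = pd.Series(cohort.clinical["stage"].to_numpy() <= 2)
        res = bulk.survival_analysis(cohort, "SLC2A1", subgroup=stage12, with_cox=False)
        assert res.metadata["n_high"] + res.metadata["n_low"] == int(stage12.sum())

    def test_empty_subgroup_rejected(self):
        cohort, _ = synthetic.simulate_bulk_cohort(100, beta=0.0, seed=22)
        empty = pd.Series(np.zeros(100, bool))
        with pytest.raises(ValueError, match="empty subgroup"):
            bulk.survival_analysis(cohort, "SLC2A1", subgroup=empty)

    def test_absent_marker_gene_rejected(self):
        cohort, _ = synthetic.simulate_bulk_cohort(100, beta=0.0, seed=23)
        with pytest.raises(KeyError, match="GHOST"):
            bulk.survival_analysis(cohort, "GHOST")
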