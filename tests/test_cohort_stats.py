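"""Association, two-sample, normality and survival statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ploidyflow.cohort import (
    build_tables,
    contingency_test,
    permutation_contingency_p,
    cox_ph,
    cox_score_test,
    km_estimate,
    log_rank_test,
    normality_check,
    welch_t_test,
)
from ploidyflow.datasets import GENOTYPE_PLOIDY_TABLE, SEX_PLOIDY_TABLE, study_cohort
from ploidyflow.simulate import CohortDesign, simulate_cohort


def exact_conditional_p(table) -> float:
    """Full enumeration of 2x2 tables with fixed margins: exact P(X^2 >= obs)."""
    table = np.asarray(table)
    r1, r2 = table.sum(axis=1)
    c1, c2 = table.sum(axis=0)
    n = table.sum()

    def pearson(a):
        t = np.array([[a, r1 - a], [c1 - a, r2 - c1 + a]], float)
        e = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
        return ((t - e) ** 2 / e).sum()

    obs = pearson(table[0, 0])
    p = 0.0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pearson(a) >= obs - 1e-12:
            p += stats.hypergeom.pmf(a, n, r1, c1)
    return float(p)


class TestContingency:
    def test_perfect_independence(self):
        res = contingency_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_published_genotype_by_ploidy_table(self):
        res = contingency_test(GENOTYPE_PLOIDY_TABLE)
        # likelihood-ratio variant reproduces the published 0.1877
        assert res.extra["likelihood_ratio_p"] == pytest.approx(0.1877, abs=1e-3)
        assert res.extra["pearson_p"] == pytest.approx(0.1877, abs=0.01)

    def test_published_sex_by_ploidy_table(self):
        res = contingency_test(SEX_PLOIDY_TABLE, method="likelihood_ratio")
        assert res.p_value == pytest.approx(0.0477, abs=1e-3)
        assert res.extra["pearson_p"] == pytest.approx(0.0477, abs=0.01)

    @pytest.mark.parametrize(
        "table", [[[3, 2], [1, 5]], [[4, 1], [2, 5]], [[2, 4], [4, 2]]]
    )
    def test_small_table_permutation_matches_enumeration(self, table):
        # the Monte-Carlo permutation p must agree with full enumeration of
        # all fixed-margin tables to within Monte-Carlo error (~3 sigma)
        p_exact = exact_conditional_p(table)
        p_mc = permutation_contingency_p(table, n_perm=20_000, seed=5)
        mc_sigma = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / 20_000)
        assert abs(p_mc - p_exact) <= 4 * mc_sigma

    def test_enumeration_oracle_total_mass(self):
        r1, r2, c1 = 5, 6, 4
        n = r1 + r2
        total = sum(
            stats.hypergeom.pmf(a, n, r1, c1)
            for a in range(max(0, c1 - r2), min(r1, c1) + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            contingency_test([[0, 0], [5, 5]])

    def test_relabeling_groups_preserves_statistic(self):
        t = [[25, 27], [18, 33]]
        a = contingency_test(t).statistic
        b = contingency_test(t[::-1]).statistic
        assert a == pytest.approx(b, rel=1e-12)


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_values(self):
        # x mean 2 var 1; y mean 4 var 4 -> t = -2/sqrt(5/3), dof = 50/17
        res = welch_t_test([1, 2, 3], [2, 4, 6])
        assert res.statistic == pytest.approx(-2 / np.sqrt(5 / 3), rel=1e-12)
        assert res.dof == pytest.approx(50 / 17, rel=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0, 1.0], [2.0, 2.0])

    def test_symmetry_under_swap(self):
        x, y = [1.0, 2.0, 5.0], [2.0, 2.5, 7.0, 9.0]
        assert welch_t_test(x, y).statistic == pytest.approx(
            -welch_t_test(y, x).statistic, rel=1e-12
        )


class TestNormality:
    def test_normal_quantile_sample_high_w(self):
        x = stats.norm.ppf((np.arange(100) + 0.5) / 100)
        assert normality_check(x).statistic > 0.99

    def test_bimodal_sample_rejected(self):
        x = np.concatenate([
            stats.norm.ppf((np.arange(50) + 0.5) / 50) - 4,
            stats.norm.ppf((np.arange(50) + 0.5) / 50) + 4,
        ])
        assert normality_check(x).p_value < 0.01

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_check(np.ones(10))

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])


class TestKaplanMeier:
    def test_uncensored_median_is_order_statistic(self):
        km = km_estimate([1, 2, 3, 4, 5])
        assert km.median == 3

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1, 2, 3], events=[False, False, False])
        assert km.median is None
        assert np.all(km.survival == 1.0)

    def test_uncensored_equals_empirical_survivor(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1.0, size=40)
        km = km_estimate(t)
        srt = np.sort(t)
        emp = 1.0 - np.searchsorted(srt, km.times, side="right") / len(t)
        np.testing.assert_allclose(km.survival, emp, atol=1e-12)

    def test_cohort_simulator_median_age(self):
        design = CohortDesign(group_sizes={"brca2_tp53": 1000}, seed=6)
        ages = [r.age_months for r in simulate_cohort(design)]
        km = km_estimate(ages)
        assert abs(km.median - 8.2) < 0.3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestLogRank:
    def test_identical_groups_null(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = log_rank_test([(g, None), (g, None)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            log_rank_test([
                ([1.0, 2.0], [False, False]),
                ([1.0, 2.0], [False, False]),
            ])

    def test_relabeling_groups_preserves_statistic(self, rng):
        t1 = rng.exponential(1.0, 15)
        t2 = rng.exponential(0.5, 15)
        a = log_rank_test([(t1, None), (t2, None)]).statistic
        b = log_rank_test([(t2, None), (t1, None)]).statistic
        assert a == pytest.approx(b, rel=1e-9)

    def test_detects_hazard_ratio_two(self, rng):
        rejections = 0
        for _ in range(20):
            t1 = rng.exponential(1.0, 200)
            t2 = rng.exponential(0.5, 200)
            if log_rank_test([(t1, None), (t2, None)]).p_value <= 0.05:
                rejections += 1
        assert rejections >= 18


class TestCox:
    def test_identical_groups_hr_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 4)
        df = pd.DataFrame({
            "age_months": t,
            "event": 1,
            "group": [0, 1] * 10,
        })
        out = cox_ph(df, ["group"])
        assert out.loc["group", "hr"] == pytest.approx(1.0, abs=0.05)

    def test_log_hazard_ratio_recovery(self):
        rng = np.random.default_rng(8)
        errors = []
        for _ in range(50):
            x = rng.integers(0, 2, size=500)
            t = rng.exponential(1.0, size=500) / np.exp(np.log(2) * x)
            df = pd.DataFrame({"age_months": t, "event": 1, "x": x})
            out = cox_ph(df, ["x"])
            errors.append(abs(out.loc["x", "log_hr"] - np.log(2)))
        assert np.median(errors) <= 0.15

    def test_score_test_equals_log_rank_without_ties(self, rng):
        t1 = rng.exponential(1.0, 25)
        t2 = rng.exponential(0.6, 25)
        times = np.concatenate([t1, t2])
        group = np.concatenate([np.zeros(25), np.ones(25)])
        score = cox_score_test(times, np.ones(50, bool), group)
        lr = log_rank_test([(t1, None), (t2, None)])
        assert abs(score.statistic - lr.statistic) < 1e-6

    def test_no_events_rejected(self):
        df = pd.DataFrame({"age_months": [1.0, 2.0], "event": 0, "x": [0, 1]})
        with pytest.raises(ValueError, match="events"):
            cox_ph(df, ["x"])


class TestBuildTables:
    def test_reconstructed_cohort_ploidy_percentages(self):
        tables = build_tables(study_cohort())
        bg = tables["ploidy_by_genotype"]
        assert bg.loc["brca2_tp53", "diploid_pct"] == 48
        assert bg.loc["brca2_tp53", "aneuploid_pct"] == 52
        assert bg.loc["tp53", "diploid_pct"] == 35
        assert bg.loc["tp53", "aneuploid_pct"] == 65
        bs = tables["ploidy_by_sex"]
        assert bs.loc["F", "diploid_pct"] == 33
        assert bs.loc["F", "aneuploid_pct"] == 67
        assert bs.loc["M", "diploid_pct"] == 52
        assert bs.loc["M", "aneuploid_pct"] == 48

    def test_reconstructed_cohort_coelomic_breakdown(self):
        loc = build_tables(study_cohort())["ploidy_by_location"]
        coel = loc[loc["location"] == "coelom"].set_index("genotype")
        assert coel.loc["brca2_tp53", "aneuploid_pct"] == 50
        assert coel.loc["brca2_tp53", "n"] == 30
        assert coel.loc["tp53", "aneuploid_pct"] == 68
        assert coel.loc["tp53", "n"] == 40

    def test_population_structure(self):
        pop = build_tables(study_cohort())["population"]
        assert pop.loc["brca2_tp53", "n_fish"] == 49
        assert pop.loc["tp53", "n_fish"] == 50
        assert pop.loc["brca2_tp53", "n_tumors"] == 52
        assert pop.loc["tp53", "n_tumors"] == 51
        assert pop.loc["brca2_tp53", "females"] == 26
        assert pop.loc["brca2_tp53", "sex_undetermined"] == 1

    def test_aneuploid_subtype_counts(self):
        bg = build_tables(study_cohort())["ploidy_by_genotype"]
        assert bg.loc["brca2_tp53", "hyperdiploid_aneuploid"] == 19
        assert bg.loc["brca2_tp53", "tetraploid_aneuploid"] == 1
        assert bg.loc["tp53", "complex_aneuploid"] == 7

    def test_empty_cohort_gives_zero_counts(self):
        empty = pd.DataFrame(
            columns=["fish_id", "genotype", "sex", "location", "age_months",
                     "event", "ploidy_category"]
        )
        tables = build_tables(empty)
        assert (tables["ploidy_by_sex"]["n"] == 0).all()
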