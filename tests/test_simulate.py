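"""Simulator ground truth: distributional targets, labels, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ploidyflow.cellcycle import make_histogram
from ploidyflow.gating import detect_histogram_peaks
from ploidyflow.simulate import (
    CohortDesign,
    PopulationSpec,
    SimulationSpec,
    SpecValidationError,
    TESTIS_COMPARTMENTS,
    simulate_cohort,
    simulate_events,
    spec_from_json,
    spec_to_json,
    testis_preset,
)


def one_pop_spec(**kw):
    defaults = dict(n_events=10_000, seed=7)
    defaults.update(kw)
    pop = PopulationSpec(dna_index=1.0, fraction=1.0, cv_pct=4.0)
    return SimulationSpec(populations=(pop,), **defaults)


def binom99(n, p):
    lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
    return lo / n, hi / n


class TestSimulateEvents:
    def test_byte_identical_under_seed(self):
        spec = one_pop_spec(debris_fraction=0.1, doublet_fraction=0.05)
        a = simulate_events(spec).to_csv(index=False)
        b = simulate_events(spec).to_csv(index=False)
        assert a == b

    def test_single_population_mean_and_cv(self):
        ev = simulate_events(one_pop_spec())
        pi = ev["PI-H"].to_numpy()
        assert abs(pi.mean() / 1e5 - 1.0) < 0.005
        cv = 100 * pi.std() / pi.mean()
        assert abs(cv - 4.0) < 0.5

    def test_two_population_mode_ratio(self):
        pops = (
            PopulationSpec(dna_index=1.0, fraction=0.5, cv_pct=3.0),
            PopulationSpec(dna_index=1.5, fraction=0.5, cv_pct=3.0),
        )
        spec = SimulationSpec(populations=pops, n_events=20_000, seed=1)
        hist = make_histogram(simulate_events(spec), bins=512)
        channels, _, _ = detect_histogram_peaks(hist)
        assert len(channels) == 2
        assert abs(channels[1] / channels[0] - 1.5) <= 0.02

    def test_debris_label_fraction_within_binomial_bounds(self):
        spec = one_pop_spec(debris_fraction=0.2)
        ev = simulate_events(spec)
        frac = ev["truth_is_debris"].mean()
        lo, hi = binom99(len(ev), 0.2)
        assert lo <= frac <= hi

    @pytest.mark.parametrize("category", ["truth_is_debris", "truth_is_doublet"])
    def test_label_conservation_across_seeds(self, category):
        p = 0.12
        kw = {"debris_fraction" if "debris" in category else "doublet_fraction": p}
        hits = 0
        for seed in range(10):
            ev = simulate_events(one_pop_spec(seed=seed, **kw))
            k = int(ev[category].sum())
            if stats.binomtest(k, len(ev), p).pvalue > 0.001:
                hits += 1
        assert hits >= 9

    def test_scaling_equivariance(self):
        lo = simulate_events(one_pop_spec(diploid_channel=1e5))
        hi = simulate_events(one_pop_spec(diploid_channel=3e5))
        q = [0.1, 0.25, 0.5, 0.75, 0.9]
        a = np.quantile(lo.loc[~lo.truth_is_debris, "PI-H"], q)
        b = np.quantile(hi.loc[~hi.truth_is_debris, "PI-H"], q)
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-9)

    def test_doublets_sum_parents_with_suppressed_height(self):
        spec = one_pop_spec(doublet_fraction=0.2)
        ev = simulate_events(spec)
        dbl = ev[ev.truth_is_doublet]
        assert len(dbl) > 100
        np.testing.assert_allclose(
            dbl["FSC-H"], 0.6 * dbl["FSC-A"], rtol=1e-9
        )
        # doublet DNA signal is the sum of two G0/G1-range draws
        assert dbl["PI-H"].mean() > 1.5e5

    @pytest.mark.parametrize(
        "bad, field",
        [
            (dict(n_events=0), "n_events"),
            (dict(diploid_channel=0.0), "diploid_channel"),
            (dict(debris_fraction=1.2), "debris_fraction"),
            (dict(debris_fraction=0.6, doublet_fraction=0.6), "doublet"),
            (dict(debris_kernel="nope"), "debris_kernel"),
        ],
    )
    def test_invalid_spec_names_field(self, bad, field):
        with pytest.raises(SpecValidationError, match=field.split("_")[0]):
            simulate_events(one_pop_spec(**bad))

    def test_population_fraction_sum_enforced(self):
        pops = (
            PopulationSpec(dna_index=1.0, fraction=0.5),
            PopulationSpec(dna_index=1.5, fraction=0.4),
        )
        with pytest.raises(SpecValidationError, match="fraction"):
            simulate_events(SimulationSpec(populations=pops, n_events=100))

    def test_phase_fraction_sum_enforced(self):
        with pytest.raises(SpecValidationError, match="frac"):
            PopulationSpec(
                dna_index=1.0, fraction=1.0, frac_g1=0.5, frac_s=0.1,
                frac_g2m=0.1,
            ).validate()


class TestSpecSerialization:
    @given(
        fracs=st.lists(st.floats(0.05, 1.0), min_size=1, max_size=3),
        dis=st.lists(st.floats(0.3, 2.5), min_size=3, max_size=3),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_spec_json_round_trip(self, fracs, dis, seed):
        total = sum(fracs)
        pops = tuple(
            PopulationSpec(dna_index=di, fraction=f / total)
            for di, f in zip(dis, fracs)
        )
        spec = SimulationSpec(populations=pops, n_events=50, seed=seed)
        spec.validate()
        assert spec_from_json(spec_to_json(spec)) == spec


class TestTestisPresets:
    def test_wild_type_haploid_modal(self):
        spec = testis_preset("wild_type")
        c = TESTIS_COMPARTMENTS["wild_type"]
        assert c["1C"] == max(c.values())
        haploid = [p for p in spec.populations if p.dna_index == 0.5][0]
        assert haploid.fraction == max(
            c["1C"], spec.populations[1].fraction * spec.populations[1].frac_g1
        )

    def test_brca2_lacks_haploid_and_accumulates_4c(self):
        c = TESTIS_COMPARTMENTS["brca2"]
        assert c["1C"] < 0.02
        assert c["4C"] == max(c.values())
        # S elevated relative to genotypes with intact spermatogenesis
        assert c["S"] > TESTIS_COMPARTMENTS["wild_type"]["S"]

    def test_brca2_tp53_diploid_modal(self):
        c = TESTIS_COMPARTMENTS["brca2_tp53"]
        assert c["1C"] < 0.02
        assert all(c["2C"] > c[k] for k in ("1C", "S", "4C"))

    def test_unknown_genotype_lists_valid_values(self):
        with pytest.raises(SpecValidationError, match="wild_type"):
            testis_preset("mystery")


class TestSimulateCohort:
    def test_aneuploid_proportions_track_sex_probabilities(self):
        design = CohortDesign(
            group_sizes={"brca2_tp53": 500, "tp53": 500}, seed=4
        )
        records = simulate_cohort(design)
        for sex, p in (("F", 0.67), ("M", 0.48)):
            sub = [r for r in records if r.sex == sex]
            frac = np.mean([r.aneuploid for r in sub])
            lo, hi = binom99(len(sub), p)
            assert lo <= frac <= hi

    def test_zero_probability_gives_all_diploid(self):
        design = CohortDesign(
            group_sizes={"tp53": 200},
            aneuploidy_p_by_sex={"F": 0.0, "M": 0.0},
            seed=1,
        )
        assert all(r.ploidy_category == "diploid" for r in simulate_cohort(design))

    def test_median_age_matches_parameter(self):
        design = CohortDesign(group_sizes={"brca2_tp53": 1000}, seed=2)
        ages = [r.age_months for r in simulate_cohort(design)]
        assert abs(np.median(ages) - 8.2) < 0.3

    def test_reproducible_under_seed(self):
        design = CohortDesign(seed=9)
        a = simulate_cohort(design)
        b = simulate_cohort(design)
        assert a == b

    def test_empty_design_rejected(self):
        with pytest.raises(SpecValidationError):
            simulate_cohort(CohortDesign(group_sizes={}))
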