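"""Ploidy decision tree: QC exclusions, reference choice, DNA index, categories."""

import numpy as np
import pytest

from ploidyflow.ploidy import (
    PloidyConfig,
    SpecimenPair,
    apply_exclusions,
    call_from_events,
    call_pair,
    classify_ploidy,
    compute_dna_index,
    select_reference,
)
from ploidyflow.simulate import simulate_pair


def pair_of(make_fit, tumor_cycles, somatic_cv=4.0, somatic_n=10_000,
            tumor_n=10_000, ambiguous=False):
    tumor = make_fit(tumor_cycles, n_events=tumor_n, ambiguous=ambiguous)
    somatic = make_fit([{"mu": 1.0e5, "cv": somatic_cv}], n_events=somatic_n)
    return SpecimenPair(fish_id="f1", tumor_fit=tumor, somatic_fit=somatic)


class TestApplyExclusions:
    def test_high_somatic_cv_excludes(self, make_fit):
        pair = pair_of(make_fit, [{"mu": 1.0e5}], somatic_cv=6.5)
        assert apply_exclusions(pair) == {"somatic_cv_gt_6", "excluded"}

    def test_cv_rule_is_strict_inequality(self, make_fit):
        pair = pair_of(make_fit, [{"mu": 1.0e5}], somatic_cv=6.0)
        assert apply_exclusions(pair) == set()

    def test_too_few_tumor_events_flagged(self, make_fit):
        pair = pair_of(make_fit, [{"mu": 1.0e5}], tumor_n=400)
        assert "insufficient_events" in apply_exclusions(pair)

    def test_missing_somatic_fit_means_no_diploid(self):
        pair = SpecimenPair(fish_id="f1")
        flags = apply_exclusions(pair)
        assert "no_diploid_definable" in flags and "excluded" in flags


class TestSelectReference:
    def test_matching_tumor_cycle_with_good_cv_is_internal(self, make_fit):
        pair = pair_of(
            make_fit,
            [
                {"mu": 1.01e5, "cv": 4.2, "cycle_fraction": 0.4},
                {"mu": 1.4e5, "cycle_fraction": 0.6},
            ],
        )
        ref, source = select_reference(pair)
        assert source == "internal_diploid"
        assert ref == pytest.approx(1.01e5)

    def test_internal_with_high_cv_falls_back_to_somatic(self, make_fit):
        pair = pair_of(
            make_fit,
            [
                {"mu": 1.0e5, "cv": 7.2, "cycle_fraction": 0.4},
                {"mu": 1.4e5, "cycle_fraction": 0.6},
            ],
        )
        ref, source = select_reference(pair)
        assert source == "matched_somatic"
        assert ref == pytest.approx(1.0e5)

    def test_minor_aneuploid_population_uses_predominant_diploid(self, make_fit):
        pair = pair_of(
            make_fit,
            [
                {"mu": 1.0e5, "cycle_fraction": 0.82},
                {"mu": 1.4e5, "cycle_fraction": 0.18},
            ],
        )
        _, source = select_reference(pair)
        assert source == "predominant_diploid"

    def test_no_internal_diploid_uses_somatic(self, make_fit):
        pair = pair_of(make_fit, [{"mu": 1.5e5}])
        ref, source = select_reference(pair)
        assert source == "matched_somatic"

    def test_no_reference_at_all_raises(self):
        with pytest.raises(ValueError, match="no_diploid_definable"):
            select_reference(SpecimenPair(fish_id="x"))


class TestComputeDNAIndex:
    def test_identity_and_ratio(self):
        assert compute_dna_index(100_000, 100_000) == 1.0
        assert compute_dna_index(200_000, 100_000) == 2.0

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_dna_index(0.0, 1e5)


class TestClassifyPloidy:
    @pytest.mark.parametrize(
        "di, expected",
        [
            (1.0, "diploid"),
            (1.04, "diploid"),
            (0.90, "hypodiploid_aneuploid"),
            (1.30, "hyperdiploid_aneuploid"),
            (2.0, "tetraploid_aneuploid"),
            (1.95, "tetraploid_aneuploid"),
            (2.3, "hyperdiploid_aneuploid"),
        ],
    )
    def test_bands(self, di, expected):
        assert classify_ploidy(di) == expected

    def test_multiple_aneuploid_peaks_mean_complex(self):
        assert classify_ploidy(None, n_aneuploid_peaks=2) == "complex_aneuploid"

    def test_undefined_index_without_multiple_peaks_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            classify_ploidy(None, n_aneuploid_peaks=1)


class TestCallPair:
    def test_clean_diploid_pair(self):
        tumor, somatic = simulate_pair(1.0, seed=21)
        call = call_from_events(tumor, somatic)
        assert call.category == "diploid"
        assert call.reference_source in ("internal_diploid", "matched_somatic")
        assert abs(call.dna_index - 1.0) <= 0.02

    def test_excluded_somatic_gets_no_category(self, make_fit):
        pair = pair_of(make_fit, [{"mu": 1.3e5}], somatic_cv=8.0)
        call = call_pair(pair)
        assert call.excluded
        assert call.category is None and call.dna_index is None

    def test_hyperdiploid_majority_clone(self):
        tumor, somatic = simulate_pair(1.4, seed=22, aneuploid_share=0.6)
        call = call_from_events(tumor, somatic)
        assert call.category == "hyperdiploid_aneuploid"
        assert abs(call.dna_index - 1.4) <= 0.02

    def test_two_aneuploid_peaks_called_complex(self, make_fit):
        pair = pair_of(
            make_fit,
            [
                {"mu": 1.0e5, "cycle_fraction": 0.4},
                {"mu": 1.3e5, "cycle_fraction": 0.3},
                {"mu": 1.6e5, "cycle_fraction": 0.3},
            ],
        )
        call = call_pair(pair)
        assert call.category == "complex_aneuploid"
        assert call.dna_index is None

    def test_minor_aneuploid_share_indexes_predominant_diploid(self, make_fit):
        pair = pair_of(
            make_fit,
            [
                {"mu": 1.0e5, "cycle_fraction": 0.82},
                {"mu": 1.4e5, "cycle_fraction": 0.18},
            ],
        )
        call = call_pair(pair)
        assert call.reference_source == "predominant_diploid"
        assert "minor_aneuploid_le_20pct" in call.qc_flags
        assert call.category == "diploid"

    def test_ambiguous_g2m_modeling_defaults_to_diploid(self, make_fit):
        pair = pair_of(
            make_fit,
            [
                {"mu": 1.0e5, "cycle_fraction": 0.6},
                {"mu": 2.0e5, "cycle_fraction": 0.4},
            ],
            ambiguous=True,
        )
        call = call_pair(pair)
        assert "ambiguous_g2m_vs_aneuploid" in call.qc_flags
        assert call.category == "diploid"

    def test_dna_index_scale_invariant(self):
        a = call_from_events(*simulate_pair(1.5, seed=23, diploid_channel=1e5))
        b = call_from_events(*simulate_pair(1.5, seed=23, diploid_channel=2.4e5))
        # independent draws at each scale: DI agrees to estimation error
        assert abs(a.dna_index - b.dna_index) <= 0.01

    def test_every_called_pair_has_one_reference_source(self, make_fit):
        pairs = [
            pair_of(make_fit, [{"mu": 1.0e5}]),
            pair_of(make_fit, [{"mu": 1.4e5}]),
            pair_of(
                make_fit,
                [
                    {"mu": 1.0e5, "cycle_fraction": 0.5},
                    {"mu": 1.4e5, "cycle_fraction": 0.5},
                ],
            ),
        ]
        for pair in pairs:
            call = call_pair(pair)
            assert not call.excluded
            assert call.reference_source in (
                "internal_diploid", "matched_somatic", "predominant_diploid",
            )
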