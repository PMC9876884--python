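"""2C/AT/GC estimation formulas, ploidy, cytotype, mixoploidy and hybrids."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ploidyflow import (
    CalibrationStandard,
    PeakEstimate,
    QCError,
    classify_hybrid,
    detect_mixoploidy,
    estimate_2c,
    estimate_at_gc,
    expected_fish_signals,
    flag_cytotypes,
    hybrid_expected_2c,
    infer_ploidy,
    monoploid_value,
)


def peak(mean, frac=0.5, qc=True, std=False):
    return PeakEstimate(mean, 0.02 * mean, 2.0, 1000, frac,
                        is_standard=std, qc_pass=qc)


class TestEstimate2C:
    @pytest.mark.parametrize(
        "sample_mean,std_mean,expected",
        [
            (1000.0, 1000.0, 2.00),   # identity ratio -> the standard's 2C
            (475.0, 1000.0, 0.95),    # guava-like ratio 0.475
            (940.0, 1000.0, 1.88),
        ],
    )
    def test_ratio_formula(self, sample_mean, std_mean, expected):
        c2 = estimate_2c(peak(sample_mean), peak(std_mean))
        assert c2 == pytest.approx(expected, abs=1e-12)

    def test_refuses_qc_failed_peak(self):
        with pytest.raises(QCError, match="sample"):
            estimate_2c(peak(500.0, qc=False), peak(1000.0))
        with pytest.raises(QCError, match="standard"):
            estimate_2c(peak(500.0), peak(1000.0, qc=False))

    @given(st.floats(0.01, 100.0))
    def test_scale_invariance(self, gain):
        base = estimate_2c(peak(480.0), peak(1000.0))
        scaled = estimate_2c(peak(480.0 * gain), peak(1000.0 * gain))
        assert scaled == pytest.approx(base, rel=1e-9)


class TestEstimateAtGc:
    def test_equal_ratios_recover_standard_at(self):
        res = estimate_at_gc(1.0, 1.0)
        assert res.at_percent == pytest.approx(64.50)
        assert res.gc_percent == pytest.approx(35.50)
        assert res.valid

    def test_cube_root_of_one_eighth_halves_at(self):
        res = estimate_at_gc(1.0, 8.0)
        assert res.at_percent == pytest.approx(64.50 / 2)

    def test_at_plus_gc_is_100_exactly(self):
        res = estimate_at_gc(0.7, 1.3)
        assert res.at_percent + res.gc_percent == 100.0

    def test_nonpositive_ratio_is_domain_error(self):
        with pytest.raises(ValueError):
            estimate_at_gc(0.0, 1.0)

    def test_at_above_100_reported_but_invalid(self):
        res = estimate_at_gc(30.0, 1.0)
        assert res.at_percent > 100 and not res.valid

    @given(st.floats(0.2, 5.0), st.floats(0.2, 5.0), st.floats(0.21, 5.0))
    def test_monotone_in_each_ratio(self, r_dapi, r_pi, r_dapi_hi):
        lo = estimate_at_gc(min(r_dapi, r_dapi_hi), r_pi).at_percent
        hi = estimate_at_gc(max(r_dapi, r_dapi_hi), r_pi).at_percent
        assert (lo < hi) == (min(r_dapi, r_dapi_hi) < max(r_dapi, r_dapi_hi)) or lo == hi


class TestPloidy:
    @pytest.mark.parametrize(
        "c2,ploidy,expected",
        [(0.95, 2, 0.475), (2.00, 4, 0.50), (3.14, 1, 3.14)],
    )
    def test_monoploid_value(self, c2, ploidy, expected):
        assert monoploid_value(c2, ploidy) == pytest.approx(expected)

    def test_monoploid_rejects_ploidy_below_1(self):
        with pytest.raises(ValueError):
            monoploid_value(1.0, 0)

    @pytest.mark.parametrize(
        "c2,ploidy,two_n",
        [(1.90, 4, 44), (0.95, 2, 22), (0.52, 1, 11), (2.85, 6, 66)],
    )
    def test_infer_ploidy_calls(self, c2, ploidy, two_n):
        call = infer_ploidy(c2, 0.475)
        assert (call.ploidy, call.two_n) == (ploidy, two_n)

    def test_ambiguity_flag_threshold(self):
        # residual 0.045 < 0.25 * 0.475 = 0.11875 -> unflagged
        assert not infer_ploidy(0.52, 0.475).ambiguous
        # halfway between 2x and 3x: residual ~0.2375 -> flagged
        assert infer_ploidy(1.19, 0.475).ambiguous

    @given(st.integers(1, 12), st.floats(0.3, 0.7))
    def test_roundtrip_on_exact_inputs(self, ploidy, cx1):
        call = infer_ploidy(ploidy * cx1, cx1)
        assert call.ploidy == ploidy and not call.ambiguous
        assert call.cx1 == pytest.approx(cx1)


class TestCytotypes:
    def test_cattleyanum_like_range_flagged(self):
        rep = flag_cytotypes([("a", 2.00), ("b", 7.03)], 0.475)
        assert rep.range_pg == pytest.approx(5.03)
        assert rep.flagged

    def test_guineense_like_range_not_flagged(self):
        rep = flag_cytotypes([("a", 1.80), ("b", 2.00)], 0.475)
        assert rep.range_pg == pytest.approx(0.20)
        assert not rep.flagged

    def test_identical_values_not_flagged(self):
        rep = flag_cytotypes([("a", 1.0), ("b", 1.0), ("c", 1.0)])
        assert rep.range_pg == 0.0 and not rep.flagged

    def test_singleton_reports_zero_range(self):
        rep = flag_cytotypes([("only", 3.0)])
        assert rep.range_pg == 0.0 and not rep.flagged

    def test_close_to_reference_uses_factor(self):
        # range 0.43 is >= 0.9 * 0.475 = 0.4275: "close to" the 1Cx
        assert flag_cytotypes([("a", 1.0), ("b", 1.43)], 0.475).flagged


class TestMixoploidy:
    def test_paper_like_mixoploid(self):
        peaks = [peak(95.0, frac=0.21), peak(190.0, frac=0.49)]
        call = detect_mixoploidy(peaks, peak(200.0, frac=0.30))
        assert call.is_mixoploid
        assert call.component_c2[0] == pytest.approx(0.95)
        assert call.component_c2[1] == pytest.approx(1.90)
        assert call.component_fractions[0] == pytest.approx(0.30)
        assert sum(call.component_fractions) == pytest.approx(1.0)

    def test_single_peak_not_mixoploid(self):
        call = detect_mixoploidy([peak(95.0)], peak(200.0))
        assert not call.is_mixoploid

    def test_minor_component_below_threshold(self):
        peaks = [peak(95.0, frac=0.95), peak(190.0, frac=0.05)]
        call = detect_mixoploidy(peaks, peak(200.0))
        assert not call.is_mixoploid

    def test_no_sample_peaks_is_error(self):
        with pytest.raises(ValueError):
            detect_mixoploidy([], peak(200.0))


class TestHybridScenarios:
    def test_guajava_guineense_expected_values(self):
        by_name = {s.name: s for s in hybrid_expected_2c(0.96, 1.90)}
        assert round(by_name["allotriploid"].expected_c2, 2) == 1.43
        assert round(by_name["allotetraploid"].expected_c2, 2) == 1.91
        assert round(by_name["allopentaploid"].expected_c2, 2) == 2.38
        assert round(by_name["allohexaploid"].expected_c2, 2) == 2.86

    def test_scenario_invariant_reduced_flags_match_arithmetic(self):
        for s in hybrid_expected_2c(1.0, 3.0):
            expected = (0.5 if s.parent_a_reduced else 1.0) * 1.0 + (
                0.5 if s.parent_b_reduced else 1.0
            ) * 3.0
            assert s.expected_c2 == pytest.approx(expected)

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    def test_parent_swap_symmetry_and_sum_identity(self, a, b):
        sa = {s.name: s.expected_c2 for s in hybrid_expected_2c(a, b)}
        sb = {s.name: s.expected_c2 for s in hybrid_expected_2c(b, a)}
        # swap exchanges the two mixed scenarios, keeps the symmetric ones
        assert sa["allotriploid"] == pytest.approx(sb["allotriploid"])
        assert sa["allohexaploid"] == pytest.approx(sb["allohexaploid"])
        assert sa["allotetraploid"] == pytest.approx(sb["allopentaploid"])
        # tri + hexa == tetra + penta == 1.5 (a + b)
        assert sa["allotriploid"] + sa["allohexaploid"] == pytest.approx(
            sa["allotetraploid"] + sa["allopentaploid"]
        )
        assert sa["allotriploid"] + sa["allohexaploid"] == pytest.approx(1.5 * (a + b))

    def test_classify_observed_190_as_allotetraploid(self):
        scen = hybrid_expected_2c(0.96, 1.90)
        assert classify_hybrid(1.90, scen, 0.10) == "allotetraploid"
        assert classify_hybrid(2.38, scen, 0.10) == "allopentaploid"

    def test_classify_midway_is_unresolved(self):
        scen = hybrid_expected_2c(0.96, 1.90)
        midway = (1.43 + 1.91) / 2
        assert classify_hybrid(midway, scen, 1.0) == "unresolved"

    def test_classify_far_from_everything_is_unresolved(self):
        scen = hybrid_expected_2c(0.96, 1.90)
        assert classify_hybrid(9.0, scen, 0.10) == "unresolved"


class TestFishSignals:
    @pytest.mark.parametrize(
        "copies,ploidy,expected",
        [(1, 2, 2), (1, 4, 4), (4, 2, 8), (4, 4, 16), (7, 1, 7)],
    )
    def test_copies_scale_with_ploidy(self, copies, ploidy, expected):
        assert expected_fish_signals(copies, ploidy) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            expected_fish_signals(0, 2)
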