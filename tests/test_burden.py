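"""PAF, attributable burden, rates, standardisation and share arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from airburden import (
    ArgumentError,
    DomainError,
    ExposureDistribution,
    RelativeRiskCurve,
    StandardPopulation,
    age_standardise,
    attributable_burden,
    compute_paf,
    percent_change,
    rate_per_100k,
    round_half_away,
    share_of_total,
)


def curve(knot_x, knot_rr, tmrel):
    return RelativeRiskCurve(np.asarray(knot_x), np.asarray(knot_rr), tmrel)


class TestComputePaf:
    def test_all_mass_at_tmrel_gives_zero(self):
        dist = ExposureDistribution([10.0], [1.0])
        rr = curve([0.0, 10.0, 50.0], [1.0, 1.0, 3.0], tmrel=10.0)
        assert compute_paf(dist, rr) == pytest.approx(0.0, abs=1e-15)

    def test_single_bin_rr_two_gives_half(self):
        dist = ExposureDistribution([20.0], [1.0])
        rr = curve([5.0, 20.0], [1.0, 2.0], tmrel=5.0)
        assert compute_paf(dist, rr) == pytest.approx(0.5)

    def test_two_bin_hand_case(self):
        # p = (0.5, 0.5), normalised RR = (1, 3): PAF = (2 - 1)/2 = 0.5
        dist = ExposureDistribution([5.0, 20.0], [0.5, 0.5])
        rr = curve([5.0, 20.0], [1.0, 3.0], tmrel=5.0)
        assert compute_paf(dist, rr) == pytest.approx(0.5)

    @pytest.mark.parametrize("p1", [round(0.1 * k, 1) for k in range(1, 10)])
    @pytest.mark.parametrize("r1", [1.0, 1.5, 2.0, 4.0])
    @pytest.mark.parametrize("r2", [1.0, 1.5, 2.0, 4.0])
    def test_two_bin_grid_matches_closed_form(self, p1, r1, r2):
        """Brute-force summation oracle over the full two-bin grid."""
        dist = ExposureDistribution([10.0, 30.0], [p1, 1 - p1])
        rr = curve([10.0, 30.0], [r1, r2], tmrel=0.0)
        # oracle: direct closed form on independently normalised RR values
        rr_at_tmrel = r1  # flat extrapolation below the first knot
        nr = np.array([r1, r2]) / rr_at_tmrel
        mean_rr = p1 * nr[0] + (1 - p1) * nr[1]
        assert compute_paf(dist, rr) == pytest.approx((mean_rr - 1) / mean_rr, abs=1e-14)

    @pytest.mark.parametrize("c", [0.1, 1.0, 7.3])
    def test_invariant_under_uniform_rr_rescaling(self, c):
        dist = ExposureDistribution([5.0, 15.0, 25.0], [0.2, 0.5, 0.3])
        base = curve([0.0, 10.0, 30.0], [1.0, 1.4, 2.5], tmrel=5.0)
        scaled = curve([0.0, 10.0, 30.0], np.array([1.0, 1.4, 2.5]) * c, tmrel=5.0)
        assert compute_paf(dist, scaled) == pytest.approx(compute_paf(dist, base), rel=1e-12)

    @given(
        shift=st.floats(0.0, 20.0),
        slope=st.floats(0.0, 0.5),
        p=st.floats(0.05, 0.95),
    )
    def test_monotone_under_rightward_shift(self, shift, slope, p):
        """With a non-decreasing RR curve, shifting exposure right never
        lowers the PAF."""
        rr = curve([0.0, 50.0], [1.0, 1.0 + slope * 50.0], tmrel=2.0)
        base = ExposureDistribution([5.0, 20.0], [p, 1 - p])
        shifted = ExposureDistribution([5.0 + shift, 20.0 + shift], [p, 1 - p])
        assert compute_paf(shifted, rr) >= compute_paf(base, rr) - 1e-12

    def test_tmrel_averaging(self):
        dist = ExposureDistribution([10.0, 30.0], [0.5, 0.5])
        rr = curve([0.0, 40.0], [1.0, 3.0], tmrel=5.0)
        avg = compute_paf(dist, rr, tmrels=[0.0, 10.0])
        parts = [
            compute_paf(dist, curve([0.0, 40.0], [1.0, 3.0], tmrel=t))
            for t in (0.0, 10.0)
        ]
        assert avg == pytest.approx(np.mean(parts))

    def test_invalid_inputs(self):
        with pytest.raises(ArgumentError):
            ExposureDistribution([10.0, 5.0], [0.5, 0.5])  # not increasing
        with pytest.raises(ArgumentError):
            ExposureDistribution([5.0, 10.0], [0.7, 0.7])  # doesn't sum to 1
        with pytest.raises(DomainError):
            curve([0.0, 10.0], [1.0, np.inf], tmrel=0.0)
        with pytest.raises(DomainError):
            curve([0.0, 10.0], [1.0, -2.0], tmrel=0.0)


class TestBurdenChain:
    def test_attributable_burden_trivial(self):
        assert attributable_burden(0.0, 12345.0) == 0.0
        assert attributable_burden(0.5, 1000.0) == 500.0

    def test_attributable_burden_composes_with_paf(self):
        dist = ExposureDistribution([5.0, 20.0], [0.5, 0.5])
        rr = curve([5.0, 20.0], [1.0, 3.0], tmrel=5.0)
        paf = compute_paf(dist, rr)
        assert attributable_burden(paf, 368006.0) == pytest.approx(184003.0)

    @given(st.floats(0.0, 0.999), st.floats(0.0, 1e7))
    def test_attributable_never_exceeds_total(self, paf, total):
        assert attributable_burden(paf, total) <= total

    def test_rates(self):
        assert rate_per_100k(500.0, 500.0) == 100000.0
        assert rate_per_100k(0.0, 1e6) == 0.0
        assert round_half_away(rate_per_100k(368006, 742_000_000), 2) == 49.60
        with pytest.raises(ArgumentError):
            rate_per_100k(1.0, 0.0)


class TestAgeStandardise:
    def test_constant_rate_is_fixed_point(self):
        std = StandardPopulation({"young": 0.3, "old": 0.7})
        assert age_standardise({"young": 12.5, "old": 12.5}, std) == pytest.approx(12.5)

    def test_hand_cases(self):
        std = StandardPopulation({"a": 1.0, "b": 0.0})
        assert age_standardise({"a": 10.0, "b": 999.0}, std) == 10.0
        std = StandardPopulation({"a": 0.6, "b": 0.4})
        assert age_standardise({"a": 10.0, "b": 100.0}, std) == pytest.approx(46.0)

    def test_band_mismatch_errors(self):
        std = StandardPopulation({"a": 0.5, "b": 0.5})
        with pytest.raises(ArgumentError):
            age_standardise({"a": 1.0, "c": 2.0}, std)

    @given(st.lists(st.floats(0.0, 1e4), min_size=2, max_size=6))
    def test_bounded_by_rate_extremes(self, rates):
        bands = [f"b{i}" for i in range(len(rates))]
        w = np.ones(len(rates)) / len(rates)
        std = StandardPopulation(dict(zip(bands, w)))
        out = age_standardise(dict(zip(bands, rates)), std)
        assert min(rates) - 1e-9 <= out <= max(rates) + 1e-9


class TestChangeAndShare:
    def test_percent_change_sign_convention(self):
        # positive = decrease
        assert percent_change(20.8, 13.8) > 0
        assert percent_change(13.8, 20.8) < 0
        assert percent_change(7.0, 7.0) == 0.0

    def test_printed_table_values(self):
        assert round_half_away(percent_change(20.8, 13.8), 1) == 33.7
        assert round_half_away(percent_change(639052, 368006), 1) == 42.4

    def test_share_of_total(self):
        assert share_of_total(5.0, 5.0) == 100.0
        assert round_half_away(share_of_total(164.3, 368.0), 1) == 44.6
        assert round_half_away(share_of_total(332.7, 368.0), 1) == 90.4

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            percent_change(0.0, 5.0)
        with pytest.raises(ArgumentError):
            share_of_total(1.0, 0.0)
        with pytest.raises(ArgumentError):
            share_of_total(-1.0, 10.0)

    def test_round_half_away_ties(self):
        assert round_half_away(2.5) == 3.0
        assert round_half_away(-2.5) == -3.0
        assert round_half_away(0.125, 2) == 0.13
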