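"""Marker-ladder calibration and hybridization-corrected lane MTL."""

import numpy as np
import pytest
from scipy import integrate

from omegaqpcr import (
    LaneProfile,
    MarkerLadder,
    fit_marker_curve,
    synth_lane,
    trf_mtl,
)
from omegaqpcr.trf_densitometry import DEFAULT_LADDER_KBP


class TestMarkerCurve:
    def test_two_point_log_linear_midpoint(self):
        ladder = MarkerLadder(entries=((1.0, 10.0), (0.1, 20.0)))
        curve = fit_marker_curve(ladder)
        assert curve.length_kbp(15.0) == pytest.approx(10**-0.5, rel=1e-9)

    def test_exact_log_linear_ladder_fits_perfectly(self, marker_curve):
        _, curve = marker_curve
        assert curve.r_squared == pytest.approx(1.0)
        for L in DEFAULT_LADDER_KBP:
            assert curve.length_kbp(curve.position(L)) == pytest.approx(L)

    def test_noisy_positions_recover_lengths_within_5pct(self):
        rng = np.random.default_rng(11)
        positions = np.array([100.0 - 40.0 * np.log10(L) for L in DEFAULT_LADDER_KBP])
        noisy = positions + rng.normal(0.0, 0.3, positions.size)
        ladder = MarkerLadder(entries=tuple(zip(DEFAULT_LADDER_KBP, noisy)))
        curve = fit_marker_curve(ladder)
        fitted = curve.length_kbp(positions)
        assert np.all(np.abs(fitted / np.array(DEFAULT_LADDER_KBP) - 1.0) < 0.05)

    def test_non_monotone_ladder_rejected(self):
        with pytest.raises(ValueError):
            MarkerLadder(entries=((2.0, 10.0), (4.0, 20.0), (1.0, 30.0)))

    def test_reciprocal_form_round_trips(self, marker_curve):
        ladder, _ = marker_curve
        curve = fit_marker_curve(ladder, form="reciprocal")
        mid = float(np.mean(ladder.positions))
        assert curve.position(curve.length_kbp(mid)) == pytest.approx(mid)


class TestTrfMtl:
    def test_two_equal_bins_hand_computed(self):
        """Equal OD at 2 and 6 kbp: MTL = 2/(1/2 + 1/6) = 3 kbp."""
        # wide exactly log-linear ladder so both bins are in range
        curve = fit_marker_curve(
            MarkerLadder(entries=((10.0, 10.0), (5.0, 22.0), (1.0, 50.0)))
        )
        positions = np.sort([curve.position(2.0), curve.position(6.0)])
        profile = LaneProfile(positions=positions, od=np.array([1.0, 1.0]))
        assert trf_mtl(profile, curve)["mtl_bp"] == pytest.approx(3000.0, rel=1e-9)

    def test_single_bin_returns_its_length(self, marker_curve):
        _, curve = marker_curve
        profile = LaneProfile(
            positions=np.array([curve.position(5.0)]), od=np.array([2.5])
        )
        assert trf_mtl(profile, curve)["mtl_bp"] == pytest.approx(5000.0)

    def test_scale_invariance_in_od(self, marker_curve):
        _, curve = marker_curve
        lane = synth_lane(curve=curve, mean_log_kbp=np.log(5.0), sd_log_kbp=0.3,
                          seed=0)
        base = trf_mtl(lane, curve)["mtl_bp"]
        scaled = LaneProfile(positions=lane.positions, od=lane.od * 37.0)
        assert trf_mtl(scaled, curve)["mtl_bp"] == pytest.approx(base, rel=1e-12)

    def test_bounded_by_nonzero_bin_lengths(self, marker_curve):
        _, curve = marker_curve
        lane = synth_lane(curve=curve, mean_log_kbp=np.log(4.0), sd_log_kbp=0.5,
                          seed=1)
        res = trf_mtl(lane, curve)
        assert res["min_length_bp"] <= res["mtl_bp"] <= res["max_length_bp"]

    def test_shift_toward_longer_fragments_increases_mtl(self, marker_curve):
        _, curve = marker_curve
        lane = synth_lane(curve=curve, mean_log_kbp=np.log(4.0), sd_log_kbp=0.2,
                          seed=2)
        base = trf_mtl(lane, curve)["mtl_bp"]
        # smaller migration = longer fragments; keep within calibrated range
        shift = -(lane.positions[1] - lane.positions[0]) * 5
        inr = (lane.positions + shift >= curve.position_range[0])
        shifted = LaneProfile(positions=lane.positions[inr] + shift,
                              od=lane.od[inr])
        assert trf_mtl(shifted, curve)["mtl_bp"] > base

    def test_correction_downweights_long_fragments(self, marker_curve):
        """On an OD-uniform smear the corrected MTL is below the naive
        OD-weighted mean length."""
        _, curve = marker_curve
        positions = np.linspace(curve.position(10.0), curve.position(2.0), 100)
        od = np.ones_like(positions)
        profile = LaneProfile(positions=positions, od=od)
        lengths = curve.length_kbp(positions) * 1e3
        naive = float(np.sum(od * lengths) / np.sum(od))
        assert trf_mtl(profile, curve)["mtl_bp"] < naive

    def test_all_zero_profile_raises(self, marker_curve):
        _, curve = marker_curve
        profile = LaneProfile(positions=np.array([50.0, 60.0]),
                              od=np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            trf_mtl(profile, curve)

    def test_out_of_range_signal_flagged(self, marker_curve):
        _, curve = marker_curve
        lo = curve.position_range[0]
        positions = np.array([lo - 5.0, lo + 1.0, lo + 2.0])
        profile = LaneProfile(positions=positions, od=np.array([1.0, 1.0, 1.0]))
        res = trf_mtl(profile, curve)
        assert res["extrapolated"]
        assert res["n_bins_used"] == 2


class TestSynthLane:
    def test_delta_recovery_within_bin_width(self, marker_curve):
        _, curve = marker_curve
        lane = synth_lane(curve=curve, delta_kbp=7.0, seed=0, n_bins=400)
        got = trf_mtl(lane, curve)["mtl_bp"]
        # one bin of migration corresponds to ~1.5% in length here
        assert got == pytest.approx(7000.0, rel=0.02)

    def test_lognormal_recovery_against_integration_oracle(self, marker_curve):
        """The corrected MTL equals the truncated distribution mean from
        direct numerical integration, within 2%."""
        _, curve = marker_curve
        mu, sigma = np.log(5.0), 0.3
        lane = synth_lane(curve=curve, mean_log_kbp=mu, sd_log_kbp=sigma,
                          n_bins=800, seed=0)
        lo = curve.length_kbp(curve.position_range[1])
        hi = curve.length_kbp(curve.position_range[0])
        pdf = lambda L: np.exp(-((np.log(L) - mu) ** 2) / (2 * sigma**2)) / (
            L * sigma * np.sqrt(2 * np.pi)
        )
        num, _ = integrate.quad(lambda L: L * pdf(L), lo, hi)
        den, _ = integrate.quad(pdf, lo, hi)
        expected = num / den * 1e3
        assert trf_mtl(lane, curve)["mtl_bp"] == pytest.approx(expected, rel=0.02)

    def test_fixed_seed_reproducible(self, marker_curve):
        _, curve = marker_curve
        kwargs = dict(curve=curve, mean_log_kbp=np.log(6.0), sd_log_kbp=0.25,
                      noise_sd=0.02, seed=42)
        a, b = synth_lane(**kwargs), synth_lane(**kwargs)
        assert np.array_equal(a.od, b.od)
        assert np.array_equal(a.positions, b.positions)

    def test_tail_background_subtraction(self, marker_curve):
        _, curve = marker_curve
        lane = synth_lane(curve=curve, mean_log_kbp=np.log(5.0), sd_log_kbp=0.2,
                          background=0.05, seed=3)
        est = LaneProfile.with_tail_background(lane.positions, lane.od)
        assert est.background == pytest.approx(0.05, abs=0.01)
        assert np.all(est.corrected_od >= 0.0)
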