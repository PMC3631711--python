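"""Filtering, differentiation, segmentation and hand-feature oracles.

Expected values come from closed-form kinematics: the minimum-jerk profile
x(tau) = D(10 tau^3 - 15 tau^4 + 6 tau^5) has peak speed 1.875 D/T at
tau = 1/2, speed 30 (D/T) tau^2 (1-tau)^2, and exactly two acceleration-
magnitude maxima at tau = (5 +/- sqrt(5))/10; the 3%-of-peak crossing
solves tau(1-tau) = sqrt(0.001875), i.e. tau = 0.045359.
"""

import numpy as np
import pytest

import sonoreach as sr
from sonoreach import kinematics as km
from sonoreach.synthetic import minimum_jerk

from conftest import FS, TAU_ONSET, minjerk_positions


def _minjerk_kin(D, T, pre_s=0.5, post_s=0.5, azimuth_deg=0.0, filtered=False):
    p = minjerk_positions(D, T, FS, pre_s, post_s, azimuth_deg)
    if filtered:
        p = km.gaussian_lowpass(p, FS)
    return km.compute_norms(p, FS), p


class TestGaussianLowpass:
    def test_constant_series_unchanged(self):
        p = np.full((120, 3), 0.87)
        out = km.gaussian_lowpass(p, FS)
        np.testing.assert_allclose(out, 0.87, atol=1e-12)

    @pytest.mark.parametrize(
        "freq,lo,hi",
        [
            (5.0, 2**-0.5 * 0.99, 2**-0.5 * 1.01),  # -3 dB at the cut-off
            (0.5, 0.99, 1.001),                      # passband essentially flat
        ],
    )
    def test_sinusoid_gain(self, freq, lo, hi):
        t = np.arange(2000) / FS
        p = np.zeros((2000, 3))
        p[:, 0] = np.sin(2 * np.pi * freq * t)
        out = km.gaussian_lowpass(p, FS)
        amp = out[500:1500, 0].max()
        assert lo <= amp <= hi

    def test_analytic_gain_matches_design(self):
        """Measured attenuation follows exp(-(2 pi f sigma)^2 / 2)."""
        sigma = km.gaussian_sigma_s(5.0)
        t = np.arange(4000) / FS
        for freq in (2.0, 5.0, 8.0):
            p = np.zeros((4000, 3))
            p[:, 1] = np.sin(2 * np.pi * freq * t)
            amp = km.gaussian_lowpass(p, FS)[1000:3000, 1].max()
            expected = np.exp(-((2 * np.pi * freq * sigma) ** 2) / 2)
            assert amp == pytest.approx(expected, rel=0.01)

    def test_too_short_series_advises_minimum_length(self):
        with pytest.raises(ValueError, match="at least"):
            km.gaussian_lowpass(np.zeros((5, 3)), FS)


class TestComputeNorms:
    def test_constant_velocity_line(self):
        t = np.arange(200) / FS
        p = np.outer(t * 0.3, np.array([0.0, 1.0, 0.0]))
        kin = km.compute_norms(p, FS)
        np.testing.assert_allclose(kin.v3D[1:-1], 0.3, atol=1e-6)
        np.testing.assert_allclose(kin.a3D[2:-2], 0.0, atol=1e-6)
        np.testing.assert_allclose(kin.j3D[3:-3], 0.0, atol=1e-4)

    def test_minimum_jerk_peak_speed(self):
        kin, _ = _minjerk_kin(0.45, 1.0)
        assert kin.v3D.max() == pytest.approx(1.875 * 0.45 / 1.0, rel=0.01)

    def test_circular_motion_speed_and_centripetal_acceleration(self):
        r, omega = 0.2, 2 * np.pi * 0.5
        t = np.arange(400) / FS
        p = np.stack([r * np.cos(omega * t), r * np.sin(omega * t), np.zeros_like(t)], 1)
        kin = km.compute_norms(p, FS)
        np.testing.assert_allclose(kin.v3D[5:-5], omega * r, rtol=0.01)
        np.testing.assert_allclose(kin.a3D[5:-5], omega**2 * r, rtol=0.01)

    def test_norms_are_nonnegative_and_same_length(self):
        kin, p = _minjerk_kin(0.3, 0.8)
        assert (kin.v3D >= 0).all() and (kin.a3D >= 0).all() and (kin.j3D >= 0).all()
        assert len(kin) == p.shape[0]

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            km.compute_norms(np.zeros((6, 3)), FS)


class TestPrimarySegment:
    def test_stationary_hand_raises_no_movement(self):
        rng = np.random.default_rng(0)
        p = rng.normal(0.0, 0.002, (300, 3))  # 2 mm jitter, within 1 cm
        with pytest.raises(km.NoMovementError):
            km.primary_segment(p, np.zeros(3))

    def test_out_and_back_window_ends_at_max_distance(self):
        p = minjerk_positions(0.45, 1.0, post_s=0.2)
        back = minjerk_positions(0.45, 1.0, post_s=0.2)[::-1]
        full = np.vstack([p, back])
        d = np.hypot(full[:, 0], full[:, 1])
        lo, hi = km.primary_segment(full, np.zeros(3))
        assert d[hi] == pytest.approx(d.max(), abs=1e-12)
        assert (d[hi + 1 :] <= d[hi] + 1e-12).all()  # return excluded
        assert d[lo] > km.DEFAULT_DISPLACEMENT_THRESHOLD_M

    def test_monotonic_outward_keeps_full_tail(self):
        p = minjerk_positions(0.45, 1.0, post_s=0.3)
        lo, hi = km.primary_segment(p, np.zeros(3))
        assert hi == p.shape[0] - 1
        d = np.hypot(p[:, 0], p[:, 1])
        assert d[lo - 1] <= km.DEFAULT_DISPLACEMENT_THRESHOLD_M < d[lo]


class TestDetectBounds:
    @pytest.mark.parametrize("D,T", [(0.45, 1.0), (0.2, 0.5), (0.6, 2.0)])
    def test_three_percent_crossings_match_root_finding(self, D, T):
        kin, _ = _minjerk_kin(D, T)
        b = km.detect_bounds(kin)
        assert b.i_start / FS - 0.5 == pytest.approx(TAU_ONSET * T, abs=1.0 / FS)
        assert b.i_end / FS - 0.5 == pytest.approx((1 - TAU_ONSET) * T, abs=1.0 / FS)

    def test_pvp_at_midpoint_by_symmetry(self):
        kin, _ = _minjerk_kin(0.45, 1.0)
        b = km.detect_bounds(kin)
        assert b.i_pvp / FS - 0.5 == pytest.approx(0.5, abs=1.0 / FS)
        assert b.v_peak == kin.v3D[b.i_pvp] == kin.v3D[b.i_start : b.i_end + 1].max()

    def test_zero_velocity_raises_no_movement(self):
        kin = km.compute_norms(np.full((50, 3), 0.3), FS)
        with pytest.raises(km.NoMovementError):
            km.detect_bounds(kin)

    def test_edge_flag_when_threshold_unreachable(self):
        # constant-speed ramp: speed never falls to 3% of its peak
        t = np.arange(100) / FS
        p = np.outer(t, np.array([0.0, 0.5, 0.0]))
        kin = km.compute_norms(p, FS)
        b = km.detect_bounds(kin)
        assert b.start_at_edge or b.end_at_edge


def _brute_peak_count(vals: np.ndarray, prom_frac: float) -> int:
    """Independent peak enumeration: strict local maxima whose prominence
    (height above the higher of the two flanking saddles) reaches
    ``prom_frac`` of the series maximum."""
    n = len(vals)
    floor = prom_frac * vals.max()
    count = 0
    for i in range(1, n - 1):
        if not (vals[i] > vals[i - 1] and vals[i] > vals[i + 1]):
            continue
        left = i
        lmin = vals[i]
        while left > 0 and vals[left - 1] <= vals[i]:
            left -= 1
            lmin = min(lmin, vals[left])
        right = i
        rmin = vals[i]
        while right < n - 1 and vals[right + 1] <= vals[i]:
            right += 1
            rmin = min(rmin, vals[right])
        lbase = lmin if left > 0 else lmin
        rbase = rmin if right < n - 1 else rmin
        if vals[i] - max(lbase, rbase) >= floor:
            count += 1
    return count


class TestHandFeatures:
    def test_pure_minimum_jerk_has_one_peak_each_side(self):
        kin, _ = _minjerk_kin(0.45, 1.0)
        b = km.detect_bounds(kin)
        f = km.hand_features(kin, b)
        assert (f.n_acc_peaks_before_pvp, f.n_acc_peaks_after_pvp) == (1, 1)
        assert f.n_acc_peaks_total == 2

    def test_straight_path_length(self):
        kin, _ = _minjerk_kin(0.45, 1.0)
        f = km.hand_features(kin, km.detect_bounds(kin))
        assert f.path_length == pytest.approx(0.450, abs=0.002)

    def test_duration_and_mean_speed_consistency(self):
        kin, _ = _minjerk_kin(0.45, 1.0)
        b = km.detect_bounds(kin)
        f = km.hand_features(kin, b)
        assert f.duration == (b.i_end - b.i_start) / FS
        assert 0.0 < f.v_mean < f.v_peak
        assert 0.0 <= f.pvp_relative_position <= 1.0

    def test_composite_submovement_matches_brute_force_enumeration(self):
        """A corrective minimum-jerk submovement in the deceleration phase
        adds after-PVP acceleration peaks; the pipeline count equals a
        brute-force enumeration on the analytic composite profile."""
        D, T, amp, d, onset = 0.45, 1.0, 0.02, 0.3, 0.7
        p = minjerk_positions(D, T)
        n = p.shape[0]
        t = np.arange(n) / FS
        sub = amp * minimum_jerk((t - 0.5 - onset * T) / d)
        p[:, 1] += sub
        kin = km.compute_norms(p, FS)
        b = km.detect_bounds(kin)
        f = km.hand_features(kin, b)
        assert f.n_acc_peaks_after_pvp > 1  # more than the unperturbed count

        brute = _brute_peak_count(
            kin.a3D[b.i_start : b.i_end + 1], km.DEFAULT_PROMINENCE_FRACTION
        )
        assert f.n_acc_peaks_total == brute


class TestInvariances:
    def test_scale_equivariance(self):
        p = minjerk_positions(0.45, 1.0, azimuth_deg=20.0)
        k = 2.7
        kin1 = km.compute_norms(p, FS)
        kin2 = km.compute_norms(k * p, FS)
        b1, b2 = km.detect_bounds(kin1), km.detect_bounds(kin2)
        f1, f2 = km.hand_features(kin1, b1), km.hand_features(kin2, b2)
        assert f2.v_peak == pytest.approx(k * f1.v_peak, rel=1e-9)
        assert f2.v_mean == pytest.approx(k * f1.v_mean, rel=1e-9)
        assert f2.path_length == pytest.approx(k * f1.path_length, rel=1e-9)
        assert f2.duration == f1.duration
        assert f2.n_acc_peaks_total == f1.n_acc_peaks_total
        assert f2.pvp_relative_position == f1.pvp_relative_position

    def test_time_shift_moves_bounds_not_features(self):
        p1 = minjerk_positions(0.45, 1.0, pre_s=0.5)
        p2 = minjerk_positions(0.45, 1.0, pre_s=0.9)
        shift = p2.shape[0] - p1.shape[0]
        kin1, kin2 = km.compute_norms(p1, FS), km.compute_norms(p2, FS)
        b1, b2 = km.detect_bounds(kin1), km.detect_bounds(kin2)
        assert (b2.i_start - b1.i_start) == shift
        assert (b2.i_end - b1.i_end) == shift
        f1, f2 = km.hand_features(kin1, b1), km.hand_features(kin2, b2)
        assert f2.duration == f1.duration
        assert f2.n_acc_peaks_total == f1.n_acc_peaks_total
        assert f2.n_acc_peaks_before_pvp == f1.n_acc_peaks_before_pvp
        assert f2.pvp_relative_position == f1.pvp_relative_position
        assert f2.v_peak == pytest.approx(f1.v_peak, rel=1e-9)
        assert f2.v_mean == pytest.approx(f1.v_mean, rel=1e-9)
        assert f2.path_length == pytest.approx(f1.path_length, rel=1e-9)

    @pytest.mark.parametrize("D", [0.2, 0.45, 0.6])
    @pytest.mark.parametrize("T", [0.5, 1.0, 2.0])
    def test_duration_and_peak_speed_across_grid(self, D, T):
        kin, _ = _minjerk_kin(D, T)
        b = km.detect_bounds(kin)
        f = km.hand_features(kin, b)
        assert f.duration == pytest.approx(T * (1 - 2 * TAU_ONSET), abs=2.0 / FS)
        assert f.v_peak == pytest.approx(1.875 * D / T, rel=0.01)

    def test_noise_robustness_at_mocap_precision(self):
        """0.25 mm white marker noise leaves path length within 2% and each
        peak count within 1 of the noise-free values (fixed seed)."""
        p = minjerk_positions(0.45, 1.0)

        def run(pp):
            pf = km.gaussian_lowpass(pp, FS)
            kin = km.compute_norms(pf, FS)
            return km.hand_features(kin, km.detect_bounds(kin))

        f0 = run(p)
        rng = np.random.default_rng(11)
        f1 = run(p + rng.normal(0.0, 2.5e-4, p.shape))
        assert abs(f1.path_length - f0.path_length) / f0.path_length < 0.02
        assert abs(f1.n_acc_peaks_before_pvp - f0.n_acc_peaks_before_pvp) <= 1
        assert abs(f1.n_acc_peaks_after_pvp - f0.n_acc_peaks_after_pvp) <= 1
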