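"""SNR gating, field-gradient correction, T2* fitting and slice summaries."""

import math

import numpy as np
import pytest

from nemri import relaxometry as rx
from nemri.phantom import (
    MULTIECHO_PROTOCOL,
    default_aorta_phantom,
    simulate_multiecho_volume,
)


class TestSnrMask:
    def test_threshold_is_inclusive_at_four(self):
        img = np.array([[100.0, 39.0], [40.0, 0.0]])
        mask = rx.snr_mask(img, noise_sigma=10.0, threshold=4.0)
        assert mask.tolist() == [[True, False], [True, False]]

    def test_zero_image_gives_empty_mask(self):
        assert not rx.snr_mask(np.zeros((8, 8)), noise_sigma=1.0).any()

    def test_background_noise_estimated_with_rayleigh_correction(self, rng):
        sigma = 5.0
        noise = np.hypot(rng.normal(0, sigma, (64, 64)), rng.normal(0, sigma, (64, 64)))
        est = rx.estimate_background_noise(noise, corner_frac=0.5)
        assert est == pytest.approx(sigma, rel=0.05)

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            rx.snr_mask(np.ones((4, 4)), noise_sigma=0.0)


class TestSincCorrection:
    def _volume(self, gz, sigma=0.0, seed=0):
        return simulate_multiecho_volume(
            [default_aorta_phantom()], gz_uT_per_mm=gz, noise_sigma=sigma, seed=seed
        )

    def test_zero_gradient_leaves_volume_unchanged(self):
        vol, _ = self._volume(0.0)
        grad = rx.FieldGradientMap(
            gz_uT_per_mm=np.zeros(vol.data.shape[1:]), slice_thickness_mm=1.0
        )
        corrected, usable, scale = rx.b0_sinc_correction(vol, grad)
        np.testing.assert_array_equal(corrected.data, vol.data)
        assert usable.all()
        assert np.all(scale == 1.0)

    def test_division_by_known_factor(self):
        vol, _ = self._volume(0.0)
        gz = np.full(vol.data.shape[1:], 0.5)
        grad = rx.FieldGradientMap(gz_uT_per_mm=gz, slice_thickness_mm=1.0)
        corrected, usable, _ = rx.b0_sinc_correction(vol, grad)
        from nemri.phantom import sinc_factor

        k = 3
        factor = sinc_factor(0.5, 1.0, vol.echo_times_ms[k])
        np.testing.assert_allclose(
            corrected.data[k][usable[k]], vol.data[k][usable[k]] * (1.0 / factor), rtol=1e-12
        )

    def test_weak_factor_echoes_dropped_not_amplified(self):
        vol, _ = self._volume(2.0)
        gz = np.full(vol.data.shape[1:], 2.0)
        grad = rx.FieldGradientMap(gz_uT_per_mm=gz, slice_thickness_mm=1.0)
        corrected, usable, _ = rx.b0_sinc_correction(vol, grad)
        assert not usable[-1].any()  # late echoes at Gz=2 are beyond recovery
        np.testing.assert_array_equal(corrected.data[-1], vol.data[-1])

    def test_correction_reduces_bias_at_every_tested_snr(self):
        """Corrected maps beat uncorrected ones at SNR 20, 50 and noiseless."""
        from nemri.experiments import sinc_correction_study

        for snr in (20.0, 50.0, np.inf):
            out = sinc_correction_study(seed=3, snr=snr)
            assert out["rmse_corrected_ms"] < out["rmse_uncorrected_ms"], snr


class TestAlignEchoes:
    def test_shift_free_volume_unmoved(self):
        vol, _ = simulate_multiecho_volume([default_aorta_phantom()], noise_sigma=0.0)
        _, max_disp = rx.align_echoes(vol)
        assert max_disp.max() < 0.05

    def test_single_voxel_shift_detected(self):
        vol, _ = simulate_multiecho_volume([default_aorta_phantom()], noise_sigma=0.0)
        data = vol.data.copy()
        data[5] = np.roll(data[5], 1, axis=1)
        shifted = rx.MultiEchoVolume(data=data, echo_times_ms=vol.echo_times_ms)
        _, max_disp = rx.align_echoes(shifted)
        assert max_disp[5] == pytest.approx(1.0, abs=0.5)

    def test_single_echo_rejected(self):
        vol = rx.MultiEchoVolume(
            data=np.ones((1, 1, 8, 8)), echo_times_ms=np.array([2.8])
        )
        with pytest.raises(ValueError, match="2 echoes"):
            rx.align_echoes(vol)


class TestT2StarFit:
    def test_two_point_closed_form(self):
        """S(2.8)=116.7, S(6.4)=58.35 -> T2* = 3.6/ln 2 = 5.194 ms."""
        s0, t2 = rx._loglinear_t2(np.array([2.8, 6.4]), np.array([116.7, 58.35]))
        assert t2 == pytest.approx(3.6 / math.log(2.0), abs=1e-3)

    def test_noiseless_voxel_recovery(self):
        vol, truth = simulate_multiecho_volume(
            [default_aorta_phantom(plaque_t2star_ms=12.0)], noise_sigma=0.0
        )
        seg = truth.t2star_ms < 100.0  # labeled organs only
        seg &= np.stack([default_aorta_phantom().labels > 0])
        t2map = rx.fit_t2star_map(vol, seg)
        rel = np.abs(t2map.t2star_ms[seg] / truth.t2star_ms[seg] - 1.0)
        assert np.nanmax(rel) < 1e-6

    def test_loglinear_and_lm_agree_on_noiseless_decay(self):
        te = MULTIECHO_PROTOCOL.echo_times_ms
        s = 120.0 * np.exp(-te / 9.0)
        s0_ll, t2_ll = rx._loglinear_t2(te, s)
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(rx._monoexp, te, s, p0=(s0_ll, t2_ll), method="lm")
        assert t2_ll == pytest.approx(popt[1], rel=1e-8)
        assert t2_ll == pytest.approx(9.0, rel=1e-10)

    def test_constant_signal_flagged_at_bound(self):
        data = np.full((15, 1, 2, 2), 50.0)
        vol = rx.MultiEchoVolume(data=data, echo_times_ms=MULTIECHO_PROTOCOL.echo_times_ms)
        t2map = rx.fit_t2star_map(vol, np.ones((1, 2, 2), dtype=bool))
        assert np.all(t2map.reason == rx.Reason.FIT_FAIL)

    def test_too_few_usable_echoes_is_fit_fail(self):
        vol, _ = simulate_multiecho_volume([default_aorta_phantom()], noise_sigma=0.0)
        usable = np.zeros_like(vol.data, dtype=bool)
        usable[:2] = True  # only two echoes usable anywhere
        seg = np.stack([default_aorta_phantom().labels > 0])
        t2map = rx.fit_t2star_map(vol, seg, usable=usable)
        assert np.all(t2map.reason[seg] == rx.Reason.FIT_FAIL)


class TestValidityFilters:
    def _map_from_values(self, values):
        arr = np.asarray(values, dtype=float).reshape(1, 3, 3)
        return rx.T2StarMap(
            t2star_ms=arr,
            s0=np.ones_like(arr),
            r_squared=np.ones_like(arr),
            reason=np.zeros_like(arr, dtype=np.int8),
        )

    def test_hand_counted_toy_map(self):
        """Values {5,10,15,20,25,29,31,35,50}: three exceed 30 ms."""
        t2map = self._map_from_values([5, 10, 15, 20, 25, 29, 31, 35, 50])
        filtered, counts = rx.apply_validity_filters(t2map, upper_limit_ms=30.0)
        assert counts["outlier"] == 3
        assert counts["kept"] == 6

    def test_boundary_is_strict(self):
        t2map = self._map_from_values([30.0, 40.0] + [10.0] * 7)
        filtered, counts = rx.apply_validity_filters(t2map)
        assert filtered.t2star_ms[0, 0, 0] == 30.0  # exactly 30 ms retained
        assert np.isnan(filtered.t2star_ms[0, 0, 1])  # 40 ms excluded

    def test_reason_counts_sum_to_total(self):
        vol, _ = simulate_multiecho_volume(
            [default_aorta_phantom()], noise_sigma=1.5, seed=9
        )
        mask = rx.snr_mask(vol.data[0, 0], noise_sigma=1.5)[None]
        t2map = rx.fit_t2star_map(vol, mask)
        _, counts = rx.apply_validity_filters(t2map)
        assert sum(counts.values()) == t2map.reason.size


class TestSliceMeans:
    def test_arithmetic_mean_of_valid_voxels(self):
        arr = np.full((1, 2, 2), np.nan)
        arr[0, 0, 0], arr[0, 0, 1] = 10.0, 20.0
        reason = np.full((1, 2, 2), int(rx.Reason.LOW_SNR), dtype=np.int8)
        reason[0, 0, :2] = rx.Reason.KEPT
        t2map = rx.T2StarMap(
            t2star_ms=arr, s0=np.ones_like(arr), r_squared=np.ones_like(arr), reason=reason
        )
        stats = rx.slice_mean_t2star(t2map)
        assert stats[0].mean_t2star_ms == 15.0
        assert stats[0].n_valid == 2

    def test_fully_excluded_slice_reported_empty(self):
        arr = np.full((1, 2, 2), np.nan)
        reason = np.full((1, 2, 2), int(rx.Reason.OUTLIER), dtype=np.int8)
        t2map = rx.T2StarMap(
            t2star_ms=arr, s0=np.ones_like(arr), r_squared=np.ones_like(arr), reason=reason
        )
        stats = rx.slice_mean_t2star(t2map)
        assert stats[0].mean_t2star_ms is None
        assert stats[0].n_valid == 0

    def test_phantom_plaque_slice_mean_within_5pct(self):
        phantom = default_aorta_phantom(plaque_t2star_ms=9.0)
        s0 = 80.0 * math.sin(math.radians(60.0)) * math.exp(-2.8 / 9.0)
        vol, _ = simulate_multiecho_volume([phantom], noise_sigma=s0 / 50.0, seed=4)
        seg = np.stack([phantom.labels == 5])
        t2map = rx.fit_t2star_map(vol, seg)
        filtered, _ = rx.apply_validity_filters(t2map)
        stats = rx.slice_mean_t2star(filtered, seg)
        assert stats[0].mean_t2star_ms == pytest.approx(9.0, rel=0.05)

    def test_timepoint_iron_load_ordering(self):
        """Slice means order baseline > 24 h > 7 h when the 7 h iron load
        exceeds the 24 h load."""
        from nemri.experiments import t2star_timepoint_ordering

        means = t2star_timepoint_ordering(seed=0)
        assert means["baseline"] > means["24h"] > means["7h"]
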