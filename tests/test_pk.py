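"""Signal normalization, concentration conversion, accumulation fitting
and the study's printed dose/ratio arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nemri import pk
from nemri.constants import FE_MOLAR_MASS
from nemri.motion import SignalTimeCourse


def _course(t, s):
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    return SignalTimeCourse(
        timestamps_min=t, mean=s, sd=np.zeros_like(s), n_voxels=np.ones_like(s, dtype=int)
    )


class TestFrameTimes:
    def test_total_scan_time_divided_by_frame_count(self):
        t = pk.estimate_frame_times(500.0, 10)
        assert np.allclose(np.diff(t), 50.0)  # 50 s per dynamic image
        t2 = pk.estimate_frame_times(600.0, 10)
        assert np.allclose(np.diff(t2), 60.0)

    def test_single_frame_centered(self):
        t = pk.estimate_frame_times(60.0, 1, offset=5.0)
        assert t.shape == (1,)
        assert t[0] == pytest.approx(35.0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            pk.estimate_frame_times(0.0, 10)
        with pytest.raises(ValueError):
            pk.estimate_frame_times(60.0, 0)


class TestFuseSessions:
    def test_injection_delay_sets_first_post_timestamp(self):
        pre = _course([0.0, 1.0, 2.0], [100, 101, 99])
        post = _course([0.0, 1.0], [90, 80])
        fused = pk.fuse_sessions(pre, post, injection_delay_min=2.0)
        assert fused.timestamps_min[fused.timestamps_min > 0][0] == pytest.approx(2.0)
        assert np.all(fused.timestamps_min[:3] < 0)

    def test_empty_post_course_rejected(self):
        pre = _course([0.0, 1.0], [100, 100])
        post = SignalTimeCourse(
            timestamps_min=np.array([]), mean=np.array([]),
            sd=np.array([]), n_voxels=np.array([], dtype=int),
        )
        with pytest.raises(ValueError, match="empty"):
            pk.fuse_sessions(pre, post, injection_delay_min=2.0)

    def test_frame_conservation(self):
        pre = _course(np.arange(8.0), np.full(8, 100.0))
        post = _course(np.arange(50.0), np.full(50, 90.0))
        fused = pk.fuse_sessions(pre, post, injection_delay_min=1.5)
        assert fused.timestamps_min.size == 58


class TestNormalization:
    def test_first_frame_mode(self):
        norm = pk.normalize_signal(_course([-2, -1, 1], [100, 90, 80]))
        assert norm.s_norm[0] == 1.0
        np.testing.assert_allclose(norm.s_norm, [1.0, 0.9, 0.8])

    def test_pre_injection_mean_mode(self):
        norm = pk.normalize_signal(
            _course([-2, -1, 1], [98, 102, 80]), baseline_mode="pre-injection-mean"
        )
        assert norm.baseline == pytest.approx(100.0)

    def test_nonpositive_baseline_rejected(self):
        course = _course([-1, 1], [1.0, 2.0])
        course.mean[0] = 0.0
        with pytest.raises(ValueError, match="baseline"):
            pk.normalize_signal(course)


class TestConcentrationConversion:
    def test_unity_signal_gives_zero_concentration(self):
        norm = pk.normalize_signal(_course([-1, 1], [100, 100]))
        conc = pk.signal_to_concentration(norm, te_ms=3.4, r2star_per_mM_s=45.0)
        assert conc.concentration_mM[0] == 0.0

    def test_direct_evaluation(self):
        """S_norm = 0.9 at TE 3.4 ms, r2* 45 -> 0.6886 mM."""
        norm = pk.normalize_signal(_course([-1, 1], [100, 90]))
        conc = pk.signal_to_concentration(norm, 3.4, 45.0)
        assert conc.concentration_mM[1] == pytest.approx(0.10536 / 0.153, abs=2e-4)

    def test_constructed_inverse_gives_one_millimolar(self):
        s = math.exp(-0.153)
        norm = pk.normalize_signal(_course([-1, 1], [1.0, s]))
        conc = pk.signal_to_concentration(norm, 3.4, 45.0)
        assert conc.concentration_mM[1] == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_signal_names_frame(self):
        norm = pk.NormalizedTimeCourse.__new__(pk.NormalizedTimeCourse)
        norm.timestamps_min = np.array([-1.0, 1.0, 2.0])
        norm.s_norm = np.array([1.0, 0.5, -0.1])
        norm.baseline = 1.0
        with pytest.raises(ValueError, match="frame 2"):
            pk.signal_to_concentration(norm, 3.4, 45.0)


def _conc_curve(t, truth_cmax, truth_tau):
    t = np.asarray(t, dtype=float)
    c = truth_cmax * (1.0 - np.exp(-truth_tau * t))
    return pk.ConcentrationCurve(
        timestamps_min=t, concentration_mM=np.where(t > 0, c, 0.0),
        te_ms=3.4, r2star_per_mM_s=45.0,
    )


class TestAccumulationFit:
    def test_noiseless_recovery_machine_precision(self):
        curve = _conc_curve(np.arange(-3.0, 48.0), 2.0, 0.05)
        fit = pk.fit_accumulation(curve)
        assert fit.success
        assert fit.cmax_mM == pytest.approx(2.0, rel=1e-6)
        assert fit.tau_per_min == pytest.approx(0.05, rel=1e-6)

    def test_five_point_recovery(self):
        curve = _conc_curve(np.array([-1.0, 2.0, 10.0, 20.0, 35.0, 47.0]), 2.0, 0.05)
        fit = pk.fit_accumulation(curve)
        assert fit.tau_per_min == pytest.approx(0.05, rel=1e-6)

    def test_constant_concentration_hits_bound_with_flag(self):
        t = np.arange(-1.0, 10.0)
        curve = pk.ConcentrationCurve(
            timestamps_min=t, concentration_mM=np.where(t > 0, 2.0, 0.0),
            te_ms=3.4, r2star_per_mM_s=45.0,
        )
        fit = pk.fit_accumulation(curve)
        assert fit.at_bound
        assert not fit.success

    def test_degenerate_data_fails_without_exception(self):
        t = np.arange(-1.0, 10.0)
        curve = pk.ConcentrationCurve(
            timestamps_min=t, concentration_mM=np.full_like(t, -0.01),
            te_ms=3.4, r2star_per_mM_s=45.0,
        )
        fit = pk.fit_accumulation(curve)
        assert not fit.success
        assert math.isnan(fit.tau_per_min)

    def test_too_few_post_injection_points_rejected(self):
        with pytest.raises(ValueError, match="4 post"):
            pk.fit_accumulation(_conc_curve(np.array([-1.0, 1.0, 2.0, 3.0]), 2.0, 0.05))

    def test_fitted_half_life_decreasing_in_true_tau(self):
        taus = [0.01, 0.02, 0.05, 0.1, 0.3]
        fitted = [
            pk.fit_accumulation(_conc_curve(np.arange(-2.0, 48.0), 2.0, tau)).half_life_min
            for tau in taus
        ]
        assert all(a > b for a, b in zip(fitted, fitted[1:]))

    def test_half_life_times_tau_is_ln2(self):
        curve = _conc_curve(np.arange(-2.0, 48.0), 2.0, 0.05)
        fit = pk.fit_accumulation(curve)
        assert fit.half_life_min * fit.tau_per_min == pytest.approx(math.log(2.0), rel=1e-15)


class TestHalfLifeArithmetic:
    def test_tau_ln2_gives_unit_half_life(self):
        assert pk.half_life(math.log(2.0)) == pytest.approx(1.0, rel=1e-15)

    @pytest.mark.parametrize(
        "tau, expected",
        [(0.0049972, 138.7), (0.0067293, 103.0)],
        ids=["stealth-formulation", "antibody-conjugated"],
    )
    def test_half_life_matches_printed_values(self, tau, expected):
        assert pk.half_life(tau) == pytest.approx(expected, abs=0.05)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            pk.half_life(0.0)

    @given(st.floats(min_value=1e-4, max_value=1e3))
    @settings(max_examples=200, deadline=None)
    def test_half_life_tau_inverse_roundtrip(self, tau):
        assert pk.tau_from_half_life(pk.half_life(tau)) == pytest.approx(tau, rel=1e-12)


class TestDoseAndRatioArithmetic:
    def test_iron_dose_conversion(self):
        """3 mg Fe/kg is 53.7 umol/kg at M(Fe) = 55.845 g/mol."""
        assert pk.convert_dose(3.0, FE_MOLAR_MASS) == pytest.approx(53.7, abs=0.05)

    def test_one_millimole_per_kg(self):
        assert pk.convert_dose(55.845, 55.845) == pytest.approx(1000.0, rel=1e-12)

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            pk.convert_dose(0.0, 55.845)

    def test_antibody_droplet_ratio_from_bulk_concentrations(self):
        """1.9 nmol/mL over 5.75e13 droplets/mL computes to ~19.9 per
        droplet (the formulation's theoretical target was 14)."""
        assert pk.antibodies_per_droplet(1.9, 5.75e13) == pytest.approx(19.9, abs=0.05)

    def test_ratio_halves_when_droplet_count_doubles(self):
        one = pk.antibodies_per_droplet(1.9, 5.75e13)
        two = pk.antibodies_per_droplet(1.9, 2 * 5.75e13)
        assert two == pytest.approx(one / 2.0, rel=1e-12)

    def test_constructed_unit_ratio(self):
        assert pk.antibodies_per_droplet(0.1, 6.02214076e13) == pytest.approx(1.0, rel=1e-12)

    def test_tocopherol_loading(self):
        assert pk.loading_mg_per_g(5.0) == 50.0


class TestRoundTrip:
    def test_forward_model_round_trip_is_exact(self, abdominal_phantom, agent):
        """Simulate -> normalize -> invert recovers C(t) to 1e-10."""
        from nemri.motion import MotionField, extract_mean_timecourse, propagate_roi
        from nemri.phantom import (
            AccumulationTruth,
            AcquisitionProtocol,
            Organ,
            simulate_dynamic_series,
        )

        truth = AccumulationTruth(cmax_mM=2.0, tau_per_min=0.05)
        series = simulate_dynamic_series(
            abdominal_phantom, AcquisitionProtocol(), agent, truth,
            noise_sigma=0.0, motion_amplitude_vox=0.0, n_post=20, seed=0,
        )
        mask = abdominal_phantom.mask(Organ.LIVER)
        static = MotionField(
            fields=np.zeros((series.frames.shape[0], 2) + mask.shape), reference_index=0
        )
        course = extract_mean_timecourse(series, propagate_roi(mask, static))
        norm = pk.normalize_signal(course)
        conc = pk.signal_to_concentration(
            norm, series.protocol.te_ms, agent.r2star_per_mM_s
        )
        np.testing.assert_allclose(
            conc.concentration_mM, series.truth.concentration_mM, atol=1e-10
        )
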