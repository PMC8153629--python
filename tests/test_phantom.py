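"""Phantom generators: label geometry, forward signal models, noise."""

import math

import numpy as np
import pytest

from nemri.phantom import (
    AccumulationTruth,
    AcquisitionProtocol,
    ContrastAgentSpec,
    Ellipse,
    Organ,
    accumulation_concentration,
    build_phantom,
    default_abdominal_phantom,
    gre_signal,
    rician,
    simulate_dynamic_series,
    simulate_esr_spectrum,
    simulate_hemolysis_curve,
    simulate_multiecho_volume,
)


class TestBuildPhantom:
    def test_default_abdominal_has_three_organs(self):
        ph = default_abdominal_phantom()
        labels = set(np.unique(ph.labels)) - {0}
        assert labels == {Organ.LIVER, Organ.KIDNEY_CORTEX, Organ.KIDNEY_PYRAMID}
        assert all(ph.mask(lab).sum() > 0 for lab in labels)

    def test_same_seed_reproduces_label_grid(self):
        a = build_phantom(
            (64, 64), [Ellipse(Organ.LIVER, (30, 30), (12, 10))], seed=3, jitter_vox=2.0
        )
        b = build_phantom(
            (64, 64), [Ellipse(Organ.LIVER, (30, 30), (12, 10))], seed=3, jitter_vox=2.0
        )
        assert np.array_equal(a.labels, b.labels)

    def test_geometry_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            build_phantom((64, 64), [Ellipse(Organ.LIVER, (5, 5), (12, 10))])

    def test_overlapping_organs_report_conflict(self):
        geoms = [
            Ellipse(Organ.LIVER, (30, 30), (12, 10)),
            Ellipse(Organ.KIDNEY_CORTEX, (34, 34), (6, 6)),
        ]
        with pytest.raises(ValueError, match="overlaps.*LIVER"):
            build_phantom((64, 64), geoms)


class TestDynamicSeries:
    def test_baseline_signal_matches_closed_form(self, abdominal_phantom, agent):
        """At C=0 the liver signal is exactly M0 sin(a) exp(-TE R2*(0))."""
        protocol = AcquisitionProtocol()
        truth = AccumulationTruth(cmax_mM=2.0, tau_per_min=0.05)
        series = simulate_dynamic_series(
            abdominal_phantom, protocol, agent, truth,
            noise_sigma=0.0, motion_amplitude_vox=0.0, seed=0,
        )
        liver = abdominal_phantom.mask(Organ.LIVER)
        expected = 100.0 * math.sin(math.radians(30.0)) * math.exp(-0.0034 * 40.0)
        pre = series.timestamps_min < 0
        vals = series.frames[pre][:, liver]
        assert np.max(np.abs(vals / expected - 1.0)) < 1e-12

    def test_concentration_truth_at_tau_t_ln2(self):
        """With tau t = ln 2 the concentration is exactly Cmax / 2."""
        truth = AccumulationTruth(cmax_mM=2.0, tau_per_min=0.05)
        t = math.log(2.0) / 0.05  # 13.863 min
        assert accumulation_concentration(t, truth) == pytest.approx(1.0, rel=1e-12)

    def test_protocol_echoed_in_metadata(self, abdominal_phantom, agent, accumulation_truth):
        protocol = AcquisitionProtocol(flip_deg=30.0, te_ms=3.4)
        series = simulate_dynamic_series(
            abdominal_phantom, protocol, agent, accumulation_truth, seed=0
        )
        assert series.meta["flip_deg"] == 30.0
        assert series.meta["te_ms"] == 3.4
        assert series.protocol is protocol

    def test_injection_gap_has_no_samples(self, abdominal_phantom, agent, accumulation_truth):
        series = simulate_dynamic_series(
            abdominal_phantom, AcquisitionProtocol(), agent, accumulation_truth,
            injection_gap_min=2.0, seed=0,
        )
        t = series.timestamps_min
        assert t[t > 0][0] == pytest.approx(2.0)
        assert not np.any((t > 0) & (t < 2.0))
        assert np.all(t[t < 0] < 0)

    def test_invalid_parameters_rejected(self, abdominal_phantom, agent, accumulation_truth):
        with pytest.raises(ValueError):
            AccumulationTruth(cmax_mM=2.0, tau_per_min=-0.1)
        with pytest.raises(ValueError, match="sigma"):
            simulate_dynamic_series(
                abdominal_phantom, AcquisitionProtocol(), agent, accumulation_truth,
                noise_sigma=-1.0,
            )

    def test_same_seed_bit_identical(self, abdominal_phantom, agent, accumulation_truth):
        kwargs = dict(noise_sigma=2.0, motion_amplitude_vox=2.0, n_post=5, seed=42)
        a = simulate_dynamic_series(
            abdominal_phantom, AcquisitionProtocol(), agent, accumulation_truth, **kwargs
        )
        b = simulate_dynamic_series(
            abdominal_phantom, AcquisitionProtocol(), agent, accumulation_truth, **kwargs
        )
        assert np.array_equal(a.frames, b.frames)

    def test_rician_mean_matches_large_snr_expansion(self, rng):
        """At SNR > 10 the sample mean approaches A + sigma^2/(2A)."""
        a, sigma = 50.0, 3.0
        draws = rician(rng, np.full((96, 96), a), sigma)
        expected = a + sigma**2 / (2 * a)
        se = sigma / math.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se

    def test_full_steady_state_reduces_to_simplified_model(
        self, abdominal_phantom, agent
    ):
        """The R2*-only model is exact at r1 = 0 and errs by only a few
        percent in normalized signal at the agent's r1 upper bound."""
        truth = AccumulationTruth(cmax_mM=2.0, tau_per_min=0.05)
        kwargs = dict(noise_sigma=0.0, motion_amplitude_vox=0.0, n_post=10, seed=0)
        simp = simulate_dynamic_series(
            abdominal_phantom, AcquisitionProtocol(), agent, truth, **kwargs
        )

        zero_r1 = ContrastAgentSpec(r1_per_mM_s=0.0)
        full0 = simulate_dynamic_series(
            abdominal_phantom, AcquisitionProtocol(), zero_r1, truth, full_model=True, **kwargs
        )
        s_rel = simp.truth.noiseless_liver_mean / simp.truth.noiseless_liver_mean[0]
        f0_rel = full0.truth.noiseless_liver_mean / full0.truth.noiseless_liver_mean[0]
        np.testing.assert_allclose(s_rel, f0_rel, rtol=1e-12)

        near_bound = ContrastAgentSpec(r1_per_mM_s=0.05)
        full = simulate_dynamic_series(
            abdominal_phantom, AcquisitionProtocol(), near_bound, truth, full_model=True, **kwargs
        )
        f_rel = full.truth.noiseless_liver_mean / full.truth.noiseless_liver_mean[0]
        assert np.max(np.abs(s_rel - f_rel)) < 0.03


class TestMultiEcho:
    def test_zero_gradient_gives_pure_monoexponential(self, aorta_phantom):
        vol, truth = simulate_multiecho_volume([aorta_phantom], noise_sigma=0.0)
        s, r, c = 0, 24, 38  # a plaque voxel
        assert aorta_phantom.labels[r, c] == Organ.PLAQUE
        sig = vol.data[:, s, r, c]
        expected = truth.s0[s, r, c] * np.exp(-vol.echo_times_ms / truth.t2star_ms[s, r, c])
        np.testing.assert_allclose(sig, expected, rtol=1e-12)

    def test_direct_signal_evaluation(self):
        """S0=200, T2*=5.194 ms: S(2.8)=116.7 and S(6.4)=58.35."""
        t2 = 3.6 / math.log(2.0)
        assert 200.0 * math.exp(-2.8 / t2) == pytest.approx(116.7, abs=0.05)
        assert 200.0 * math.exp(-6.4 / t2) == pytest.approx(58.35, abs=0.05)

    def test_echo_train_arithmetic(self, aorta_phantom):
        vol, _ = simulate_multiecho_volume([aorta_phantom])
        assert vol.n_echoes == 15
        assert vol.echo_times_ms[-1] == pytest.approx(2.8 + 14 * 3.6)  # 53.2 ms

    def test_nonpositive_t2star_rejected(self, aorta_phantom):
        from dataclasses import replace

        from nemri.phantom import TissueState

        with pytest.raises(ValueError):
            TissueState(m0=80.0, r1=1.0, r2star_baseline=-5.0)
        # echo count precondition
        with pytest.raises(ValueError, match="3 echoes"):
            simulate_multiecho_volume(
                [aorta_phantom],
                protocol=replace(
                    AcquisitionProtocol(), n_echoes=2, delta_te_ms=3.6, te_ms=2.8, tr_ms=1300.0
                ),
            )


class TestESRSpectrumGenerator:
    def test_zero_concentration_is_flat(self):
        spec, _ = simulate_esr_spectrum(0.0, noise_sigma=0.0)
        assert np.all(spec.intensity == 0.0)

    def test_double_integral_linear_in_concentration(self):
        from nemri.esr import double_integral

        s1, _ = simulate_esr_spectrum(1e-8, noise_sigma=0.0)
        s2, _ = simulate_esr_spectrum(2e-8, noise_sigma=0.0)
        assert double_integral(s2) == pytest.approx(2.0 * double_integral(s1), rel=1e-10)

    def test_gaussian_derivative_extrema_at_center_plus_minus_sigma(self):
        spec, _ = simulate_esr_spectrum(1e-8, center_mT=320.0, pp_width_mT=80.0)
        b_max = spec.field_mT[np.argmax(spec.intensity)]
        b_min = spec.field_mT[np.argmin(spec.intensity)]
        assert b_max == pytest.approx(280.0, abs=0.7)
        assert b_min == pytest.approx(360.0, abs=0.7)

    def test_narrow_axis_rejected(self):
        with pytest.raises(ValueError, match="too narrow"):
            simulate_esr_spectrum(1e-8, field_mT=np.arange(300.0, 340.0, 0.7))


class TestHemolysisGenerator:
    def test_logistic_midpoint_is_t50(self):
        curve, _ = simulate_hemolysis_curve(100.0, time_min=np.arange(0.0, 300.0, 1.0))
        assert curve.hemolysis_pct[curve.time_min == 100.0][0] == pytest.approx(50.0)

    def test_large_steepness_approaches_step(self):
        curve, _ = simulate_hemolysis_curve(100.0, steepness_per_min=50.0)
        assert curve.hemolysis_pct[curve.time_min == 99.0][0] < 1e-6
        assert curve.hemolysis_pct[curve.time_min == 101.0][0] > 100.0 - 1e-6

    def test_crossing_times_shift_with_t50(self):
        from nemri.krl import t50_hemolysis

        a, _ = simulate_hemolysis_curve(100.0)
        b, _ = simulate_hemolysis_curve(80.0)
        ta, _ = t50_hemolysis(a)
        tb, _ = t50_hemolysis(b)
        assert ta - tb == pytest.approx(20.0, abs=0.01)

    def test_grid_never_reaching_crossing_rejected(self):
        with pytest.raises(ValueError, match="50%"):
            simulate_hemolysis_curve(100.0, time_min=np.arange(0.0, 50.0, 1.0))
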