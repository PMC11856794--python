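import numpy as np
import pytest

from cantibeat import synthetic as syn
from cantibeat.errors import InstabilityError, ParameterError
from cantibeat.reconstruction import ForceTrace
from cantibeat.spectral import DisplacementTrace


class TestTwitchGenerator:
    def test_peaks_reach_amplitude(self):
        params = syn.ventricular_preset()
        t = np.arange(0.0, 10.0, 1e-4)
        f = syn.twitch_force(params, t)
        # 10 beats, each peaking at the configured amplitude
        for k in range(10):
            seg = f.values[(t >= k) & (t < k + 1)]
            assert seg.max() == pytest.approx(params.amplitude, rel=1e-5)

    def test_waveform_is_continuous_across_periods(self):
        params = syn.ventricular_preset()
        eps = 1e-9
        end = params.periodic_shape(np.array([params.period - eps]))[0]
        start = params.periodic_shape(np.array([0.0]))[0]
        assert abs(end - start) < 1e-3

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ParameterError, match="relax"):
            syn.TwitchParams(beat_rate=5.0, rise_tau=0.1, decay_tau=0.18)
        with pytest.raises(ParameterError):
            syn.TwitchParams(amplitude=0.0)

    def test_preset_ordering_of_normalized_kinetics(self):
        """Atrial-like kinetics: faster velocities, smaller force-time
        integral (normalised) than ventricular-like kinetics."""
        ta = syn.twitch_truth_metrics(syn.atrial_preset())
        tv = syn.twitch_truth_metrics(syn.ventricular_preset())
        assert ta["F_c_norm"] > tv["F_c_norm"]
        assert ta["F_r_norm"] > tv["F_r_norm"]
        assert ta["FI_norm"] < tv["FI_norm"]

    def test_truth_metrics_satisfy_identities(self):
        m = syn.twitch_truth_metrics(syn.atrial_preset())
        assert m["F_c"] == pytest.approx(
            0.8 * m["B_m"] / (m["T_m"] - m["T_1"]), rel=1e-9
        )
        assert m["FI"] <= m["B_m"] * (m["T_2"] - m["T_1"])

    def test_ramp_envelope_soft_start(self):
        params = syn.ventricular_preset()
        t = np.arange(0.0, 5.0, 1e-3)
        f = syn.twitch_force(params, t, ramp_beats=2)
        assert f.values[t < 0.5].max() < 0.6 * params.amplitude
        assert f.values[t > 3.0].max() == pytest.approx(params.amplitude, rel=1e-4)


class TestBeamOracle:
    def test_zero_force_stays_at_rest(self, compliant_spec):
        t = np.arange(0.0, 1.0, 1e-3)
        out = syn.simulate_cantilever_fd(
            ForceTrace(t, np.zeros_like(t)), compliant_spec,
            syn.BeamSimConfig(dt=1e-3),
        )
        assert np.max(np.abs(out.values)) == 0.0

    def test_static_tip_deflection_converges_with_grid(self, compliant_spec):
        """Held tip load: FD deflection approaches P L^3/(3EI), improving
        monotonically with spatial resolution."""
        exact = 1e-5 * compliant_spec.length**3 / (
            3 * compliant_spec.flexural_rigidity
        )
        errs = []
        for n in (25, 50, 100):
            tip = syn.static_shape(compliant_spec, 1e-5, n)[-1]
            errs.append(abs(tip - exact) / exact)
        assert errs[0] < 5e-3
        assert errs[0] > errs[1] > errs[2]

    def test_free_vibration_frequency_matches_closed_form(self, compliant_spec):
        """Release from a bent shape: the dominant tip frequency must match
        f1 = (1.8751^2/2pi) sqrt(EI/rho A)/L^2 within 1%."""
        y0 = syn.static_shape(compliant_spec, 1e-5, 50)
        t = np.arange(0.0, 10.0, 1e-3)
        out = syn.simulate_cantilever_fd(
            ForceTrace(t, np.zeros_like(t)),
            compliant_spec,
            syn.BeamSimConfig(dt=1e-3, output_fs=200.0),
            initial_displacement=y0,
        )
        x = out.values - out.values.mean()
        mag = np.abs(np.fft.rfft(x * np.hanning(x.size)))
        k = int(np.argmax(mag[1:])) + 1
        d = 0.5 * (mag[k - 1] - mag[k + 1]) / (mag[k - 1] - 2 * mag[k] + mag[k + 1])
        f_est = (k + d) * 200.0 / x.size
        f1 = compliant_spec.clamped_free_frequency_hz()
        assert abs(f_est - f1) / f1 < 0.01

    def test_instability_detected(self, compliant_spec):
        t = np.arange(0.0, 5.0, 1e-3)
        f = ForceTrace(t, 1e-6 * np.sin(2 * np.pi * t))
        with pytest.raises(InstabilityError):
            syn.simulate_cantilever_fd(
                f, compliant_spec, syn.BeamSimConfig(dt=1e-3, mass_damping=-40.0)
            )

    def test_energy_diagnostics_reported(self, compliant_spec):
        t = np.arange(0.0, 2.0, 1e-3)
        f = ForceTrace(t, 1e-6 * np.ones_like(t))
        out = syn.simulate_cantilever_fd(f, compliant_spec, syn.BeamSimConfig(dt=1e-3))
        assert {"work_in_J", "kinetic_J", "strain_J"} <= out.meta["energy"].keys()


class TestMeasurementNoise:
    def test_same_seed_reproduces_exactly(self):
        tr = DisplacementTrace.from_samples(np.linspace(0, 1e-6, 300))
        a = syn.add_measurement_noise(tr, seed=9)
        b = syn.add_measurement_noise(tr, seed=9)
        assert np.array_equal(a.values, b.values)
        assert a.meta["measurement_noise"]["seed"] == 9

    def test_fine_grid_zero_sigma_is_near_identity(self):
        tr = DisplacementTrace.from_samples(np.linspace(0, 1e-6, 300))
        out = syn.add_measurement_noise(tr, pixel_scale=1e-15, sigma_px=0.0, seed=0)
        assert np.max(np.abs(out.values - tr.values)) < 1e-12

    def test_invalid_pixel_scale(self):
        tr = DisplacementTrace.from_samples(np.zeros(10))
        with pytest.raises(ParameterError):
            syn.add_measurement_noise(tr, pixel_scale=0.0)

    def test_noise_only_reconstructs_to_zero_mean_force(self, stiff_spec):
        """Pure measurement noise must not fabricate net force: across 100
        seeds the mean reconstructed force is within 2 SE of zero."""
        from cantibeat.reconstruction import displacement_to_force

        tr = DisplacementTrace.from_samples(np.zeros(240))
        means = []
        for seed in range(100):
            noisy = syn.add_measurement_noise(tr, seed=seed)
            out = displacement_to_force(noisy, stiff_spec)
            means.append(np.mean(out.values))
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean()) < 2 * se + 1e-18


class TestRenderer:
    def test_zero_trace_renders_identical_frames(self):
        tr = DisplacementTrace.from_samples(np.zeros(5))
        frames, truth = syn.render_frames(tr)
        assert np.all(frames == frames[0])
        assert np.allclose(np.diff(truth), 0.0)

    def test_tip_out_of_frame_rejected(self):
        cfg = syn.RenderConfig()
        huge = DisplacementTrace.from_samples(
            np.full(4, cfg.height * cfg.pixel_scale)
        )
        with pytest.raises(ParameterError, match="frame"):
            syn.render_frames(huge, cfg)

    def test_tiff_roundtrip_lossless(self, tmp_path):
        from cantibeat.tracking import read_stack, write_stack

        tr = DisplacementTrace.from_samples(
            2 * syn.DEFAULT_PIXEL_SCALE * np.sin(np.linspace(0, 6, 8))
        )
        frames, _ = syn.render_frames(tr)
        p = tmp_path / "stack.tif"
        write_stack(frames, p)
        assert np.array_equal(read_stack(p), frames)


class TestStimulusSchedule:
    def test_locked_identities(self):
        s = syn.StimulusSchedule(motor_rate=5.0)
        assert s.stretch_frequency_hz == 5.0
        assert s.period_s == pytest.approx(0.2)
        assert s.pulse_period_s == s.period_s
        assert s.pulse_frequency_hz == s.stretch_frequency_hz

    @pytest.mark.parametrize(
        "rate, tau, expected_pairs",
        [(1.0, 0.5, 1), (5.0, 0.1, 5)],
    )
    def test_operating_points_one_pair_per_cycle(self, rate, tau, expected_pairs):
        """The two bioreactor operating points: one coordinated
        stretch/pulse pair per motor rotation, strain peak 0.05, 100 mV
        pulses of 1 ms."""
        sched = syn.StimulusSchedule(
            motor_rate=rate, stretch_width=tau, max_strain=0.05,
            pulse_amplitude_mv=100.0, pulse_width_ms=1.0, phase_ms=0.0,
        )
        t, strain, pulse = syn.stimulus_timeline(sched, duration=1.0, sample_rate=50_000)
        d = syn.describe_timeline(t, strain, pulse)
        assert d["n_stretch_events"] == expected_pairs
        assert d["n_pulse_events"] == expected_pairs
        assert d["strain_peak"] == pytest.approx(0.05, rel=1e-3)
        assert d["pulse_amplitude_mV"] == pytest.approx(100.0)
        assert d["pulse_width_ms"] == pytest.approx(1.0, rel=0.05)
        assert d["stretch_width_s"] == pytest.approx(tau, rel=0.01)

    def test_phase_delays_pulse_to_mid_cycle(self):
        sched = syn.StimulusSchedule(motor_rate=1.0, phase_ms=500.0)
        t, strain, pulse = syn.stimulus_timeline(sched, 1.0, 10_000)
        on = t[pulse > 0]
        assert on.min() == pytest.approx(0.5, abs=1e-3)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ParameterError):
            syn.StimulusSchedule(motor_rate=0.0)
        with pytest.raises(ParameterError):
            syn.StimulusSchedule(motor_rate=1.0, phase_ms=1500.0)
        with pytest.raises(ParameterError):
            syn.StimulusSchedule(motor_rate=5.0, pulse_width_ms=300.0)
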