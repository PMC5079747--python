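import numpy as np
import pytest

from mfca3 import (
    FeatureConfig,
    StimulusProtocol,
    Sweep,
    SynapseModelParams,
    detect_action_currents,
    detect_spikes,
    event_features,
    extract_recording_features,
    fit_exponential,
    lowpass_1khz,
    max_slope,
    measure_onset,
    simulate_experiment,
    single_stimulus_plan,
)
from mfca3.synthetic_data import _spike_waveform
from mfca3.trace_features import train_charge


def make_sweep(samples, role="postsynaptic_voltage", dt=0.02):
    return Sweep(np.asarray(samples, float), dt=dt, channel_role=role)


class TestLowpass:
    def test_dc_gain_is_unity(self):
        sw = make_sweep(np.full(5000, 3.7))
        np.testing.assert_allclose(lowpass_1khz(sw).samples, 3.7, rtol=1e-9)

    def test_passband_sinusoid_barely_attenuated(self):
        t = np.arange(0, 200, 0.02)  # ms
        sw = make_sweep(np.sin(2 * np.pi * 0.1 * t))  # 100 Hz
        out = lowpass_1khz(sw).samples
        mid = slice(2000, -2000)
        assert np.abs(out[mid]).max() == pytest.approx(1.0, abs=0.02)

    def test_minus_3db_at_cutoff(self):
        t = np.arange(0, 200, 0.02)
        sw = make_sweep(np.sin(2 * np.pi * 1.0 * t))  # 1 kHz
        out = lowpass_1khz(sw).samples
        mid = slice(2000, -2000)
        assert np.abs(out[mid]).max() == pytest.approx(2 ** -0.5, rel=0.05)

    def test_noise_power_reduced(self, rng):
        sw = make_sweep(rng.normal(0, 1, 20000))
        assert lowpass_1khz(sw).samples.std() < sw.samples.std()

    def test_too_coarse_sampling_rejected(self):
        with pytest.raises(ValueError):
            lowpass_1khz(make_sweep(np.zeros(100), dt=0.5))


class TestMaxSlope:
    def test_linear_ramp_slope_exact(self):
        t = np.arange(0, 20, 0.02)
        sw = make_sweep(2.9 * t)
        s, _ = max_slope(sw, (1.0, 19.0))
        assert s == pytest.approx(2.9, rel=1e-12)

    def test_constant_trace_slope_zero(self):
        sw = make_sweep(np.full(1000, -70.0))
        s, _ = max_slope(sw, (1.0, 19.0))
        assert s == 0.0

    @pytest.mark.parametrize("f_hz", [20.0, 50.0, 100.0])
    def test_sine_slope_matches_analytic(self, f_hz):
        t = np.arange(0, 100, 0.02)
        A = 5.0
        sw = make_sweep(A * np.sin(2 * np.pi * f_hz / 1000.0 * t))
        s, st = max_slope(sw, (1.0, 99.0))
        assert s == pytest.approx(2 * np.pi * f_hz / 1000.0 * A, rel=0.01)

    def test_tie_broken_by_earliest_time(self):
        y = np.zeros(1000)
        y[100:200] = np.arange(100) * 0.5  # constant slope segment
        sw = make_sweep(y)
        _, st = max_slope(sw, (0.5, 19.0))
        assert st <= 100 * 0.02 + 0.1

    def test_window_must_exceed_derivative_span(self):
        sw = make_sweep(np.zeros(1000), dt=0.04)  # 25 kHz: span 60us < 2*dt
        with pytest.raises(ValueError):
            max_slope(sw, (1.0, 19.0))


class TestFitExponential:
    def test_single_component_noiseless_exact(self):
        t = np.arange(0, 500, 1.0)
        y = 5.0 * np.exp(-t / 89.0)
        fit = fit_exponential(t, y, 1, with_offset=False)
        assert fit.success
        assert fit.taus[0] == pytest.approx(89.0, rel=1e-6)

    def test_offset_recovered(self):
        t = np.arange(0, 400, 0.5)
        y = 4.0 * np.exp(-t / 50.0) + 2.0
        fit = fit_exponential(t, y, 1, with_offset=True)
        assert fit.taus[0] == pytest.approx(50.0, rel=1e-6)
        assert fit.offset == pytest.approx(2.0, abs=1e-6)

    def test_two_components_recovered(self):
        t = np.arange(0, 600, 0.5)
        y = 3.0 * np.exp(-t / 10.0) + 1.0 * np.exp(-t / 100.0)
        fit = fit_exponential(t, y, 2, with_offset=True)
        assert fit.success
        np.testing.assert_allclose(sorted(fit.taus), [10.0, 100.0], rtol=0.01)

    def test_constant_input_reports_offset(self):
        t = np.arange(0, 50, 1.0)
        fit = fit_exponential(t, np.full_like(t, 3.3), 1, with_offset=True)
        assert fit.success
        assert fit.offset == pytest.approx(3.3)
        assert abs(fit.amplitudes[0]) < 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(np.arange(5.0), np.arange(5.0), 1)


class TestOnset:
    def test_linear_ramp_onset_at_foot(self):
        # baseline 0 until t*=25 ms, then a linear rise: the 20-80% chord of a
        # line passes through its own foot
        t = np.arange(0, 50, 0.02)
        y = np.where(t > 25.0, (t - 25.0) * 2.0, 0.0)
        sw = make_sweep(y)
        cfg = FeatureConfig(filter_voltage=False, peak_window_ms=12.0)
        onset = measure_onset(sw, 20.0, config=cfg)
        assert onset == pytest.approx(25.0, abs=0.02)

    def test_step_event_onset_within_one_sample(self):
        t = np.arange(0, 50, 0.02)
        y = np.where(t >= 25.0, 8.0, 0.0)
        sw = make_sweep(y)
        cfg = FeatureConfig(filter_voltage=False, peak_window_ms=10.0)
        onset = measure_onset(sw, 20.0, config=cfg)
        assert onset == pytest.approx(25.0, abs=0.04)

    def test_simulated_epsp_latency_matches_generator(self, noiseless_single_features):
        v = noiseless_single_features.query("channel_role == 'postsynaptic_voltage'")
        assert v.latency_ms.mean() == pytest.approx(1.06, abs=0.05)


class TestEventFeatures:
    def test_rectangular_pulse_charge_1pC(self):
        # 100 pA for 10 ms = 1.0 pC
        t = np.arange(0, 100, 0.02)
        y = np.where((t >= 21.0) & (t < 31.0), 100.0, 0.0)
        sw = make_sweep(y, role="postsynaptic_current")
        feats = event_features(sw, 20.0)
        assert feats.charge == pytest.approx(1.0, rel=0.01)
        assert feats.peak_amplitude == pytest.approx(100.0, rel=0.01)

    def test_train_charge_of_rectangle(self):
        t = np.arange(0, 100, 0.02)
        y = np.where((t >= 21.0) & (t < 31.0), -100.0, 0.0)  # inward current
        sw = make_sweep(y, role="postsynaptic_current")
        proto = StimulusProtocol.train(1, start=20.0)
        assert train_charge(sw, proto) == pytest.approx(1.0, rel=0.01)

    def test_noiseless_simulated_epsp_kinetics(self, noiseless_single_features):
        """Defaults recovered: 9.6 mV, 3.6 ms rise, 134 ms decay within 1%."""
        v = noiseless_single_features.query("channel_role == 'postsynaptic_voltage'")
        assert v.amplitude.mean() == pytest.approx(9.6, rel=0.01)
        assert v.rise_time_20_80_ms.mean() == pytest.approx(3.6, rel=0.01)
        assert v.decay_tau_ms.mean() == pytest.approx(134.0, rel=0.01)
        assert not v.is_failure.any()

    def test_noiseless_simulated_epsc_kinetics(self, noiseless_single_features):
        c = noiseless_single_features.query("channel_role == 'postsynaptic_current'")
        assert c.amplitude.mean() == pytest.approx(100.0, rel=0.01)
        assert c.rise_time_20_80_ms.mean() == pytest.approx(0.65, rel=0.01)
        assert c.decay_tau_ms.mean() == pytest.approx(6.5, rel=0.01)
        assert (c.polarity == -1).all()  # EPSCs are inward

    def test_translation_equivariance(self):
        p = SynapseModelParams(noise_sd=0.0, failure_prob=0.0)
        plan = single_stimulus_plan(n_trials=1, params=p, sweep_duration=300.0,
                                    channels=("postsynaptic_voltage",), seed=2)
        rec, _ = simulate_experiment(plan)
        sw = rec[0]["postsynaptic_voltage"]
        delta = 10.0  # ms
        k = int(delta / sw.dt)
        shifted = sw.copy_with(np.concatenate([np.full(k, sw.samples[0]),
                                               sw.samples[:-k]]))
        a = event_features(sw, 20.0)
        b = event_features(shifted, 20.0 + delta)
        assert b.onset_time == pytest.approx(a.onset_time + delta, abs=0.02)
        assert b.peak_time == pytest.approx(a.peak_time + delta, abs=0.02)
        assert b.latency == pytest.approx(a.latency, abs=0.02)
        assert b.peak_amplitude == pytest.approx(a.peak_amplitude, rel=1e-6)
        assert b.rise_time_20_80 == pytest.approx(a.rise_time_20_80, abs=0.02)

    def test_amplitude_and_charge_linear_in_scaling(self):
        t = np.arange(0, 200, 0.02)
        y = -80.0 * np.exp(-np.maximum(t - 21.0, 0) / 8.0) * (t >= 21.0)
        sw = make_sweep(y, role="postsynaptic_current")
        a = event_features(sw, 20.0)
        b = event_features(sw.copy_with(3.0 * y), 20.0)
        assert b.peak_amplitude == pytest.approx(3.0 * a.peak_amplitude, rel=1e-9)
        assert b.charge == pytest.approx(3.0 * a.charge, rel=1e-9)

    def test_flat_trace_classified_as_failure(self, rng):
        y = rng.normal(0, 0.3, 5000)
        sw = make_sweep(y)
        feats = event_features(sw, 20.0)
        assert feats.is_failure
        assert np.isnan(feats.peak_amplitude)


class TestSpikesAndActionCurrents:
    def test_pasted_spike_detected_at_3_1_ms(self):
        # stereotyped spike 3.1 ms after the stimulus on a quiet trace
        sw_samples = np.full(5000, -70.0)
        wave = _spike_waveform(0.02, 100.0, 2.0)
        i0 = int(round(23.1 / 0.02))
        sw_samples[i0 : i0 + wave.size] += wave
        sw = make_sweep(sw_samples)
        proto = StimulusProtocol.train(1, start=20.0)
        events, flags = detect_spikes(sw, proto)
        assert flags.tolist() == [True]
        assert len(events) == 1
        assert events[0].latency_to_onset == pytest.approx(3.1, abs=0.25)

    def test_subthreshold_epsp_yields_no_spike(self, noiseless_single_rec):
        rec, _ = noiseless_single_rec
        sw = rec[0]["postsynaptic_voltage"]
        events, flags = detect_spikes(sw, rec[0].protocol)
        assert events == [] and not flags.any()

    def test_spike_matrix_matches_ground_truth(self, noiseless_ptp):
        rec, truth = noiseless_ptp
        df = extract_recording_features(rec)
        v = df[df.channel_role == "postsynaptic_voltage"]
        det = v.pivot_table(index="trial_index", columns="stim_index",
                            values="spike", aggfunc="first").to_numpy().astype(bool)
        tm = truth[truth.trial_index.isin(v.trial_index.unique())].pivot_table(
            index="trial_index", columns="stim_index", values="spike",
            aggfunc="first").to_numpy().astype(bool)
        np.testing.assert_array_equal(det, tm)

    def test_action_currents_all_detected(self, noiseless_single_rec):
        rec, _ = noiseless_single_rec
        for trial in rec:
            flags = detect_action_currents(trial["presynaptic_current"], trial.protocol)
            assert flags.all()

    def test_flat_presynaptic_trace_all_false(self):
        sw = make_sweep(np.zeros(5000), role="presynaptic_current")
        proto = StimulusProtocol.train(3, 50.0, start=20.0)
        assert not detect_action_currents(sw, proto).any()


class TestNoisyRecovery:
    def test_median_errors_small_at_half_mV_noise(self):
        """50 noisy trials: median |err| < 5% (amplitude, decay tau), < 0.1 ms
        (latency)."""
        p = SynapseModelParams(noise_sd=0.5, failure_prob=0.0)
        plan = single_stimulus_plan(n_trials=50, params=p,
                                    channels=("postsynaptic_voltage",), seed=21)
        rec, _ = simulate_experiment(plan)
        df = extract_recording_features(rec)
        v = df[df.channel_role == "postsynaptic_voltage"]
        assert np.median(np.abs(v.amplitude - 9.6) / 9.6) < 0.05
        assert np.median(np.abs(v.decay_tau_ms - 134.0) / 134.0) < 0.05
        assert np.median(np.abs(v.latency_ms - 1.06)) < 0.1
        assert not v.is_failure.any()
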