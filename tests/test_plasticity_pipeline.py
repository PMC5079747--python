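import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from mfca3 import (
    SynapseModelParams,
    analyze_ptp_experiment,
    detonation_time_course,
    facilitation_ratios,
    ptp_time_course,
    simulate_experiment,
    spike_probability,
    summary_stats,
    triplet_plan,
)
from mfca3.plasticity_pipeline import InsufficientDataError


class TestFacilitation:
    def test_single_trial_printed_ratios(self):
        res = facilitation_ratios(np.array([[100.0, 257.0, 312.0]]))
        np.testing.assert_allclose(res.ratios, [1.0, 2.57, 3.12])

    def test_equal_amplitudes_give_unity(self):
        res = facilitation_ratios(np.full((5, 3), 80.0))
        np.testing.assert_allclose(res.ratios, 1.0)
        np.testing.assert_allclose(res.ratio_sem, 0.0)

    def test_zero_first_amplitude_rejected(self):
        with pytest.raises(ZeroDivisionError):
            facilitation_ratios(np.array([[0.0, 10.0]]))

    def test_noisy_simulation_recovers_generative_ratios(self):
        """50 noisy EPSC triplets recover multipliers (1, 2.5, 3)."""
        from mfca3 import extract_recording_features

        p = SynapseModelParams(
            noise_sd_current=5.0, failure_prob=0.0,
            facilitation_ratios=(1.0, 2.5, 3.0),
        )
        plan = triplet_plan(n_trials=50, params=p, channels=("postsynaptic_current",),
                            sweep_duration=150.0, seed=31)
        rec, _ = simulate_experiment(plan)
        df = extract_recording_features(rec)
        amp = df.pivot_table(index="trial_index", columns="stim_index",
                             values="amplitude").to_numpy()
        res = facilitation_ratios(amp)
        for r, target in zip(res.ratios[1:], (2.5, 3.0)):
            assert r == pytest.approx(target, abs=0.05)


class TestSpikeProbability:
    def test_counting(self):
        m = np.zeros((10, 3), dtype=bool)
        m[0, 0] = True
        res = spike_probability(m)
        np.testing.assert_allclose(res.probabilities, [0.1, 0.0, 0.0])
        assert res.n_trials == 10

    def test_all_spikes_on_third(self):
        m = np.zeros((7, 3), dtype=bool)
        m[:, 2] = True
        assert spike_probability(m).probabilities[2] == 1.0

    def test_empty_period_rejected(self):
        with pytest.raises(InsufficientDataError):
            spike_probability(np.zeros((4, 3), bool), np.zeros(4, bool))

    @given(
        arrays(bool, st.tuples(st.integers(1, 12), st.integers(1, 4))),
    )
    def test_matches_brute_force_recount(self, m):
        res = spike_probability(m)
        brute = [
            sum(1 for trial in m if trial[j]) / m.shape[0]
            for j in range(m.shape[1])
        ]
        np.testing.assert_allclose(res.probabilities, brute)


class TestPtpTimeCourse:
    def schedule(self):
        base_t = np.arange(-200.0, 0.0, 20.0)
        post_t = np.arange(20.0, 320.0, 20.0)
        return base_t, post_t

    def test_flat_series_reports_100_percent(self):
        base_t, post_t = self.schedule()
        t = np.concatenate([base_t, post_t])
        res = ptp_time_course(t, np.full(t.size, 2.9), hfs_end_s=0.0)
        assert res.peak_percent == pytest.approx(100.0)
        assert res.window_mean_percent == pytest.approx(100.0)
        assert not res.fit_ok  # degenerate decay flagged, not fabricated

    def test_closed_form_series_recovered_exactly(self):
        """Series 1 + 3.42 exp(-(t-22)/89) -> peak 442%, tau 89 s, window mean
        equal to the analytic mean at the sampled points."""
        base_t, post_t = self.schedule()
        t = np.concatenate([base_t, post_t])
        s0 = 2.9
        norm = 1.0 + 3.42 * np.exp(-np.maximum(t - 22.0, 0.0) / 89.0)
        norm[t < 0] = 1.0
        res = ptp_time_course(t, s0 * norm, hfs_end_s=0.0)
        assert res.peak_percent == pytest.approx(442.0, rel=1e-9)
        assert res.decay_tau_s == pytest.approx(89.0, rel=1e-6)
        in_win = (post_t >= 22.0) & (post_t <= 122.0)
        expected = 100.0 * np.mean(1.0 + 3.42 * np.exp(-(post_t[in_win] - 22.0) / 89.0))
        assert res.window_mean_percent == pytest.approx(expected, rel=1e-9)

    def test_window_interval_is_closed(self):
        t = np.array([-40.0, -20.0, 22.0, 70.0, 122.0, 150.0])
        y = np.array([1.0, 1.0, 4.0, 2.0, 1.5, 1.2])
        res = ptp_time_course(t, y, hfs_end_s=0.0)
        # trials at exactly 22 s and 122 s are inside the window
        expected = 100.0 * np.mean([4.0, 2.0, 1.5])
        assert res.window_mean_percent == pytest.approx(expected)

    def test_scaling_invariance(self):
        base_t, post_t = self.schedule()
        t = np.concatenate([base_t, post_t])
        y = 1.0 + 3.0 * np.exp(-np.maximum(t, 0.0) / 60.0) * (t > 0)
        a = ptp_time_course(t, y, hfs_end_s=0.0)
        b = ptp_time_course(t, 7.3 * y, hfs_end_s=0.0)
        assert b.peak_percent == pytest.approx(a.peak_percent, rel=1e-12)
        np.testing.assert_allclose(b.normalized, a.normalized)

    def test_requires_baseline_and_window_trials(self):
        with pytest.raises(InsufficientDataError):
            ptp_time_course(np.array([10.0, 30.0]), np.array([1.0, 2.0]), hfs_end_s=0.0)


class TestDetonation:
    def test_no_spikes_flat_zero(self):
        t = np.concatenate([np.arange(-100, 0, 20.0), np.arange(20, 200, 20.0)])
        res = detonation_time_course(t, np.zeros(t.size, bool), hfs_end_s=0.0)
        assert res.baseline_probability == 0.0
        np.testing.assert_allclose(res.probabilities, 0.0)
        assert not res.fit_ok and "no post-tetanus spikes" in res.fit_message

    def test_all_spikes_flat_one(self):
        t = np.concatenate([np.arange(-100, 0, 20.0), np.arange(20, 200, 20.0)])
        res = detonation_time_course(t, np.ones(t.size, bool), hfs_end_s=0.0)
        assert res.baseline_probability == 1.0
        np.testing.assert_allclose(res.probabilities, 1.0)
        assert not res.fit_ok  # degenerate: already at baseline

    def test_binning_averages_probabilities(self):
        t = np.concatenate([np.arange(-40, 0, 20.0), np.arange(10, 90, 10.0)])
        s = np.zeros(t.size, bool)
        s[t > 0] = np.array([1, 1, 1, 0, 1, 0, 0, 0], bool)
        res = detonation_time_course(t, s, hfs_end_s=0.0, bin_s=20.0)
        assert res.probabilities.max() <= 1.0
        assert res.times_since_hfs_s.size < (t > 0).sum()


class TestSummaryStats:
    def test_mean_and_sem(self):
        res = summary_stats(np.array([1.0, 2.0, 3.0]))
        assert res.mean == pytest.approx(2.0)
        assert res.sem == pytest.approx(1.0 / np.sqrt(3.0), abs=1e-3)

    def test_identical_pairs_give_p_one(self):
        a = np.array([0.1, 0.5, 0.9])
        res = summary_stats(a, paired_with=a.copy())
        assert res.p_value == 1.0 and res.t_statistic == 0.0

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            summary_stats(np.array([1.0]))

    def test_power_for_detonation_effect(self, rng):
        """7 pairs with a true control-vs-PTP difference reach p < 0.05 in at
        least 80% of seeded replicates."""
        hits = 0
        for _ in range(100):
            control = rng.binomial(10, 0.14, size=7) / 10.0
            ptp = rng.binomial(5, 0.71, size=7) / 5.0
            if summary_stats(ptp, paired_with=control).p_value < 0.05:
                hits += 1
        assert hits >= 80


class TestExperimentAnalysis:
    def test_detonation_switch_visible_in_report(self, noiseless_ptp):
        rec, _ = noiseless_ptp
        rep = analyze_ptp_experiment(rec)
        assert rep.detonation.window_probability > rep.detonation.baseline_probability
        assert rep.window_spikes.probabilities[0] > rep.control_spikes.probabilities[0]

    def test_ptp_parameters_recovered(self, noiseless_ptp):
        rec, _ = noiseless_ptp
        rep = analyze_ptp_experiment(rec)
        assert rep.ptp.peak_percent == pytest.approx(442.0, rel=0.01)
        assert abs(rep.ptp.decay_tau_s - 89.0) <= 2.0
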