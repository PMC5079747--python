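import numpy as np
import pytest
from hypothesis import settings

from mfca3 import (
    SynapseModelParams,
    analyze_ptp_experiment,
    extract_recording_features,
    ptp_experiment_plan,
    simulate_experiment,
    single_stimulus_plan,
)

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noiseless_params():
    return SynapseModelParams(noise_sd=0.0, noise_sd_current=0.0, failure_prob=0.0)


@pytest.fixture(scope="session")
def noiseless_single_rec(noiseless_params):
    """10 noiseless single-stimulus trials with all three channels."""
    plan = single_stimulus_plan(
        n_trials=10,
        params=noiseless_params,
        channels=("presynaptic_current", "postsynaptic_voltage", "postsynaptic_current"),
        seed=1,
    )
    return simulate_experiment(plan)


@pytest.fixture(scope="session")
def noiseless_single_features(noiseless_single_rec):
    rec, _ = noiseless_single_rec
    return extract_recording_features(rec)


@pytest.fixture(scope="session")
def noiseless_ptp(noiseless_params):
    """Noiseless PTP-induction experiment (baseline trains, tetanus, recovery)."""
    rec, truth = simulate_experiment(ptp_experiment_plan(params=noiseless_params, seed=3))
    return rec, truth


@pytest.fixture(scope="session")
def noisy_ptp_reports():
    """20 seeded PTP experiments at 0.5 mV recording noise, analyzed."""
    reports = []
    for seed in range(20):
        params = SynapseModelParams(noise_sd=0.5, failure_prob=0.0)
        rec, _ = simulate_experiment(ptp_experiment_plan(params=params, seed=seed))
        reports.append(analyze_ptp_experiment(rec))
    return reports


@pytest.fixture
def rng():
    return np.random.default_rng(42)
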