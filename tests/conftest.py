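import numpy as np
import pytest

from sparsepk import ErrorModel, default_truth, preprocess_arm, simulate_study

# Reported mouse disposition truths used throughout the suite.
CAB_TRUTH = dict(A=16621.0, alpha=4.52, B=30206.0, beta=0.053, dose_ug=66.0)
MPA_TRUTH = dict(A=2506.0, alpha=10.5, B=439.0, beta=0.65, dose_ug=65.0)


def biexp(t, A, alpha, B, beta, **_):
    t = np.asarray(t, dtype=float)
    return A * np.exp(-alpha * t) + B * np.exp(-beta * t)


@pytest.fixture(scope="session")
def cab_noise_free_arm():
    truth = default_truth("CAB").replace(error_model=ErrorModel("power", 0.0))
    return simulate_study(truth)


@pytest.fixture(scope="session")
def mpa_noise_free_arm():
    truth = default_truth("MPA").replace(error_model=ErrorModel("log_additive", 0.0))
    return simulate_study(truth)


@pytest.fixture(scope="session")
def cab_noisy_arm():
    """One preprocessed CAB IV arm with 10% proportional noise."""
    truth = default_truth("CAB").replace(error_model=ErrorModel("power", 0.1))
    arm, _ = preprocess_arm(simulate_study(truth, seed=42))
    return arm
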