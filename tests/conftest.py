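import numpy as np
import pytest

from careshift import (
    CapacitanceParams,
    CountSeries,
    MotionProfile,
    TransductionParams,
    default_layout,
    simulate_counts,
    simulate_trial,
)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def cap_params():
    return CapacitanceParams()


@pytest.fixture(scope="session")
def noiseless_tp():
    return TransductionParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_counts(layout, noiseless_tp):
    """Default centred trial count stream, noise-free."""
    return simulate_counts(MotionProfile(), layout, trans_params=noiseless_tp)


@pytest.fixture(scope="session")
def default_trial():
    """One complete trial with default (noisy) parameters, seed 0."""
    return simulate_trial(seed=0)


def make_counts(matrix, fs=62.0):
    """CountSeries from a plain matrix with generated timestamps."""
    matrix = np.asarray(matrix, dtype=float)
    return CountSeries(fs=fs, t=np.arange(matrix.shape[0]) / fs, counts=matrix)


@pytest.fixture
def counts_factory():
    return make_counts
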