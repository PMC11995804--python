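import numpy as np
import pytest

from megprog import cohort as ch
from megprog import wavelets as wv


@pytest.fixture(scope="session")
def tiny_spec():
    """A small planted-effect cohort spec used across the suite."""
    return ch.reduced_spec(n_prog=12, n_stable=10, n_sensors=12,
                           n_epochs=3, epoch_len_s=4.0, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return ch.simulate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_layout(tiny_spec):
    return ch.make_layout(tiny_spec.n_sensors, tiny_spec.seed)


@pytest.fixture(scope="session")
def tiny_family(tiny_spec):
    # 4-45 Hz so every wavelet has valid samples on the 4 s epochs
    return wv.build_wavelet_family(4.0, 45.0, 0.35, 0.35, tiny_spec.fs)


@pytest.fixture(scope="session")
def tiny_tensors(tiny_cohort, tiny_family):
    return wv.cohort_spectral_tensors(tiny_cohort, tiny_family)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
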