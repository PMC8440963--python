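import numpy as np
import pytest

from eegrefine.montage import default_montage
from eegrefine.network import default_spec, train
from eegrefine.representation import build_tensor, electrode_stats, standardize
from eegrefine.synth import SimConfig, simulate


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def small_set():
    """Compact but fully structured synthetic set (24 trials, 1 s epochs)."""
    return simulate(SimConfig(n_trials_per_class=6, duration=1.0, seed=7))


@pytest.fixture(scope="session")
def small_batch(small_set):
    b = build_tensor(small_set)
    stats = electrode_stats(b, small_set.electrodes)
    return standardize(b, stats, small_set.electrodes)


@pytest.fixture(scope="session")
def trained_small(small_batch):
    """One short training run shared by inference/attribution tests."""
    spec = default_spec(small_batch.input_shape, seed=7, epochs=8)
    return train(spec, small_batch, None)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
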