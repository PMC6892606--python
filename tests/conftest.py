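import numpy as np
import pytest

from optospread import synthgen
from optospread.core import PhotostimProtocol


@pytest.fixture(scope="session")
def protocol():
    return PhotostimProtocol(duration_s=1.0, ramp_ms=0.0)


@pytest.fixture(scope="session")
def small_dataset(protocol):
    """Compact suppression dataset: 4 distances, PYR + FS, 20 trials."""
    cfg = synthgen.SuppressionConfig(
        center_reduction=0.9, lateral_sigma_mm=0.68,
        n_units_per_distance=6, n_fs_per_distance=2,
        distances_mm=(0.0, 0.5, 1.0, 2.0), n_trials=20,
        stim_duration_s=1.0, seed=42)
    return synthgen.simulate_suppression_dataset(cfg, protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
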