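import numpy as np
import pytest

from affordmap.graph import build_graph
from affordmap.simulate import GenerativeConfig


@pytest.fixture(scope="session")
def graph():
    """Full-size task graph: 36 modules starting at 21."""
    return build_graph(21, 36)


@pytest.fixture(scope="session")
def small_graph():
    return build_graph(21, 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_fmri_config():
    """Scaled-down fMRI generative settings used by simulation tests."""
    return GenerativeConfig(
        n_subjects=4, n_runs=4, n_trials=20, n_probe=4, n_voxels=16,
        gaze_runs=1, gaze_hz=500.0,
    )
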