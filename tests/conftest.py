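import numpy as np
import pytest

from pulvicon.datatypes import SimulationConfig


@pytest.fixture
def small_config():
    """Reduced simulation: 4 subjects, 10 areas in 2 networks, small grid."""
    areas = [f"v{i}" for i in range(6)] + [f"d{i}" for i in range(4)]
    nets = {a: ("ventral" if a.startswith("v") else "dorsal") for a in areas}
    return SimulationConfig(
        n_subjects=4, area_names=areas, network_assignment=nets,
        grid_shape=(2, 4, 4), n_timepoints=120, bilateral=False,
        area_corr_length=2.0, topography_corr=0.25, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
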