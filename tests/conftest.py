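import numpy as np
import pytest

from quiescore.presets import build_preset
from quiescore.render import FieldLayout
from quiescore.simulate import simulate_timepoint


@pytest.fixture(scope="session")
def sen3_cells():
    """Mixed-state per-cell table: every phenotype present, all markers bimodal."""
    return simulate_timepoint("SEN3", 1000, seed=11)


@pytest.fixture(scope="session")
def sen3_preset():
    return build_preset("SEN3")


@pytest.fixture
def small_layout():
    """A quick-to-render field for unit tests."""
    return FieldLayout(shape=(256, 256), nucleus_radius_um=(4.0, 6.0), max_cells=25)


@pytest.fixture
def quiet_layout():
    """Small field with all noise sources off (blur retained)."""
    return FieldLayout(
        shape=(256, 256),
        nucleus_radius_um=(4.0, 6.0),
        max_cells=25,
        shot_noise=False,
        read_noise_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
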