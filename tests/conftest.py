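import numpy as np
import pytest

from spexi import SystemGeometry
from spexi import synthetic as syn


@pytest.fixture(scope="session")
def geometry():
    """Default system: Si(111), Se K-edge, 9 um pixels, 500 mm focus-detector."""
    return SystemGeometry()


@pytest.fixture(scope="session")
def edge_sim(geometry):
    """Noiseless calibration-only simulation on a narrow detector."""
    stacks, truth = syn.simulate_scan(None, geometry, noise=False, n_cols=24, seed=7)
    return stacks, truth


@pytest.fixture(scope="session")
def small_scan(geometry):
    """Noiseless 12-angle CT scan of the three-species phantom (small width)."""
    phantom = syn.make_demo_phantom("three_species_disks", width=96)
    stacks, truth = syn.simulate_scan(
        phantom, geometry, n_angles=12, noise=False, decay_to=1.0, seed=3
    )
    return phantom, stacks, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
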