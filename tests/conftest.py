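import numpy as np
import pytest
from hypothesis import settings

import kbsolv as kb

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_box():
    return kb.Box([4.0, 4.0, 4.0])


@pytest.fixture()
def tiny_trajectory(rng, small_box):
    """3 frames of 6 single-atom molecules (two species), wrapped coords."""
    coords = rng.uniform(0, 4.0, size=(3, 6, 3))
    topo = kb.monatomic_topology({"alpha": 3, "beta": 3})
    return kb.Trajectory(coords, np.arange(3.0), small_box, topo)


@pytest.fixture()
def hb_scene_pair():
    """One clearly bonded and one angle-rejected geometry."""
    return kb.gen_hb_scene([(170.0, 200.0), (120.0, 200.0)])
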