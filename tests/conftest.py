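import numpy as np
import pytest

from zfschool import BodyPose, SimulationConfig, VisualObject


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def vr_config():
    return SimulationConfig()


@pytest.fixture
def group_config():
    return SimulationConfig.group_defaults()


@pytest.fixture
def origin_pose():
    return BodyPose(0.0, 0.0, 0.0)


def random_scene(rng, n_objects, spread=2.0, h_range=(0.05, 0.5)):
    """Random dot scene around (but not on top of) the origin."""
    objs = []
    for k in range(n_objects):
        while True:
            x, y = rng.uniform(-spread, spread, 2)
            if np.hypot(x, y) > 0.6:
                break
        objs.append(
            VisualObject(x, y, half_extent=rng.uniform(*h_range), obj_id=k + 1)
        )
    return objs
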