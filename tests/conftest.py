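import numpy as np
import pytest

from mmphantom import phantom as ph
from mmphantom.modality import default_property_table


@pytest.fixture(scope="session")
def small_config():
    # compact grid keeps the suite fast while containing every organ
    return ph.PhantomConfig(shape=(48, 48, 48), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return ph.generate_phantom(small_config, seed=7)


@pytest.fixture(scope="session")
def breathing_pair(small_config):
    motion = ph.MotionParameters(diaphragm_motion_mm=12.0, chest_expansion_mm=5.0)
    return ph.make_breathing_pair(small_config, motion, seed=7)


@pytest.fixture(scope="session")
def property_table():
    return default_property_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
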