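import math

import numpy as np
import pytest

from osteoscan.geometry import RigidTransform2D
from osteoscan.phantom import PhantomSpec, make_misaligned_pair


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(snr=math.inf, fat_shift_px=0.0)


@pytest.fixture(scope="session")
def misaligned_bundle():
    """One phantom sample with a known (7 deg, 4 px, -2 px) misalignment."""
    return make_misaligned_pair(
        PhantomSpec(misalignment=RigidTransform2D(7.0, 4.0, -2.0), seed=3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
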