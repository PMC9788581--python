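import numpy as np
import pytest
from hypothesis import settings

from skelburden.registration import RigidTransform
from skelburden.synthetic import PhantomSpec, make_phantom

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: small grid on which per-voxel Python-loop oracles stay fast
SMALL_SHAPE = (16, 16, 24)


@pytest.fixture(scope="session")
def small_phantom():
    """One lesion-bearing phantom on the oracle-sized grid, no misalignment."""
    spec = PhantomSpec(grid_shape=SMALL_SHAPE, lesion_count=3, seed=7)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """A default-grid phantom with a handful of lesions."""
    spec = PhantomSpec(lesion_count=6, seed=42)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def lesion_free_phantom():
    spec = PhantomSpec(grid_shape=SMALL_SHAPE, lesion_count=0, seed=5)
    return make_phantom(spec)


def volume_center(spec: PhantomSpec) -> tuple:
    ext = np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
    return tuple(ext / 2.0)


def transform_action_error(t1: RigidTransform, t2: RigidTransform, points) -> float:
    """Max displacement discrepancy (mm) of two transforms over probe points."""
    return float(np.linalg.norm(t1.apply(points) - t2.apply(points), axis=1).max())
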