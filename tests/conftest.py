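import numpy as np
import pytest

from pregdose.phantom import build_reference_scene
from pregdose.transport import TransportConfig, TransportProblem
from pregdose.voxelize import adjust_scene_masses, voxelize_scene


@pytest.fixture(scope="session")
def minimal_scene():
    return build_reference_scene("minimal_test")


@pytest.fixture(scope="session")
def reference_scene():
    return build_reference_scene("reference_9mo")


@pytest.fixture(scope="session")
def minimal_lattice(minimal_scene):
    lat = voxelize_scene(minimal_scene, 4.0)
    adjust_scene_masses(minimal_scene, lat)
    return lat


@pytest.fixture(scope="session")
def minimal_problem(minimal_scene, minimal_lattice):
    return TransportProblem.from_scene(minimal_scene, minimal_lattice)


@pytest.fixture(scope="session")
def coarse_reference_problem(reference_scene):
    """Reference scene voxelized at 4 mm: coarse but fast, with every organ
    present, for dose-assembly tests that need fetal source regions."""
    lat = voxelize_scene(reference_scene, 4.0)
    adjust_scene_masses(reference_scene, lat)
    return TransportProblem.from_scene(reference_scene, lat)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
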