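import numpy as np
import pytest

from deva import (
    ScaffoldContext,
    make_tetrahedral_site,
    make_toy_scaffold,
    plant_pocket,
)

POCKET = (4, 6, 21, 23)


@pytest.fixture(scope="session")
def his2cys2_site():
    return make_tetrahedral_site(
        [("HIS", "NE2"), ("HIS", "NE2"), ("CYS", "SG"), ("CYS", "SG")]
    )


@pytest.fixture(scope="session")
def compact_scaffold():
    return make_toy_scaffold(30, "compact_cluster")


@pytest.fixture(scope="session")
def helix_scaffold():
    return make_toy_scaffold(30, "helix")


@pytest.fixture(scope="session")
def planted_scaffold():
    return plant_pocket(make_toy_scaffold(30, "hairpin"), POCKET)


@pytest.fixture(scope="session")
def planted_context(planted_scaffold):
    return ScaffoldContext(planted_scaffold)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
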