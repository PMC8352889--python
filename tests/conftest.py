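import numpy as np
import pytest

from footmetry.mesh_core import BoneMesh, FootModel, GroundPlane
from footmetry.synthetic_foot import default_templates, generate_foot


@pytest.fixture()
def tetra_mesh() -> BoneMesh:
    """Unit tetrahedron: the smallest closed mesh."""
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return BoneMesh("CA", v, f)


@pytest.fixture()
def flat_ground() -> GroundPlane:
    return GroundPlane(point=np.zeros(3), up=np.array([0.0, 0.0, 1.0]))


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def flat_template(templates):
    return templates[1]


@pytest.fixture(scope="session")
def normal_template(templates):
    return templates[0]


@pytest.fixture(scope="session")
def template_foot(flat_template):
    """Noiseless flatfoot-template foot with its closed-form truth."""
    return generate_foot(flat_template)


def make_tetra(label: str, center, scale: float = 4.0,
               side: str = "RIGHT") -> BoneMesh:
    v = scale * np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
                         dtype=float) + np.asarray(center, dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return BoneMesh(label, v, f, side=side)


@pytest.fixture()
def stub_foot_factory(flat_ground):
    """Factory for minimal FootModels built from tetrahedral stand-in bones
    (synthetic stubs; geometry only has to satisfy the structural
    invariants, not anatomy)."""

    def build(m2_center=(140.0, 0.0, 5.0)):
        centers = {
            "TI": (40, 5, 100), "CA": (20, 0, 2), "TA": (50, 5, 40),
            "NA": (80, 10, 25), "CU": (80, -15, 19), "CM": (100, 12, 19),
            "M1": (130, 20, 6), "M2": m2_center,
        }
        bones = {k: make_tetra(k, c) for k, c in centers.items()}
        return FootModel("stub", "RIGHT", bones, flat_ground)

    return build
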