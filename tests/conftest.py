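import numpy as np
import pytest

from modecross import enm
from modecross.fixtures import FixtureSpec, make_backbone
from modecross.structure_io import Atom, Structure


@pytest.fixture(scope="session")
def helix():
    return make_backbone(FixtureSpec("helix", 12))


@pytest.fixture(scope="session")
def hinge():
    return make_backbone(FixtureSpec("two_segment_hinge", 10))


@pytest.fixture(scope="session")
def hairpin():
    return make_backbone(FixtureSpec("hairpin", 8))


@pytest.fixture(scope="session")
def complex_pose():
    return make_backbone(FixtureSpec("complex_pose", 10))


@pytest.fixture(scope="session")
def hinge_modes(hinge):
    return enm.compute_modes(hinge, 3, cutoff=8.0)


def random_structure(n_atoms: int, seed: int, density: float = 0.04) -> Structure:
    """Uniform random atoms in a cube at roughly constant number density."""
    rng = np.random.default_rng(seed)
    edge = max(8.0, (n_atoms / density) ** (1.0 / 3.0))
    coords = rng.uniform(0.0, edge, size=(n_atoms, 3))
    elements = rng.choice(["C", "N", "O", "S"], size=n_atoms)
    atoms = [
        Atom(serial=i + 1, name=f"{elements[i]}{i % 9 + 1}", element=elements[i],
             res_name="ALA", chain_id="A", res_seq=i // 4 + 1, i_code="",
             coord=coords[i])
        for i in range(n_atoms)
    ]
    return Structure(atoms, id=f"random-{n_atoms}-{seed}")
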