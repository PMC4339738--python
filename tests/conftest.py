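"""Shared fixtures: tiny synthetic structures and geometry helpers."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from flexcmp import CalphaStructure, FixtureSpec, make_structure
from flexcmp.structures import THREE_TO_ONE, residue_mass

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}


def structure_from_coords(coords, structure_id="toy", sequence=None):
    """Build a CalphaStructure from raw nm coordinates.

    ``sequence`` (one-letter) defaults to poly-alanine.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    seq = sequence or "A" * n
    labels = [
        ("A", i + 1, "", ONE_TO_THREE.get(c, "UNK")) for i, c in enumerate(seq)
    ]
    masses = np.array([residue_mass(c) for c in seq])
    return CalphaStructure(
        structure_id=structure_id,
        residue_labels=labels,
        coordinates=coords,
        masses=masses,
    )


def random_rigid_transform(seed):
    """Seeded random rotation matrix and translation vector (nm)."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-2.0, 2.0, size=3)
    return rot, trans


def transformed(structure, seed):
    rot, trans = random_rigid_transform(seed)
    return structure.with_coordinates(structure.coordinates @ rot.T + trans)


@pytest.fixture
def dimer():
    """Two unit-mass-equivalent beads 0.35 nm apart along x."""
    return structure_from_coords(
        [[0.0, 0.0, 0.0], [0.35, 0.0, 0.0]], structure_id="dimer"
    )


@pytest.fixture
def collinear3():
    return structure_from_coords(
        [[0.0, 0.0, 0.0], [0.38, 0.0, 0.0], [0.76, 0.0, 0.0]],
        structure_id="chain3",
    )


@pytest.fixture(scope="session")
def blob10():
    return make_structure(FixtureSpec(kind="compact_blob", n_residues=10, seed=42))


@pytest.fixture(scope="session")
def blob20():
    return make_structure(FixtureSpec(kind="compact_blob", n_residues=20, seed=7))


@pytest.fixture(scope="session")
def helix20():
    return make_structure(FixtureSpec(kind="helix", n_residues=20, seed=0))


@pytest.fixture(scope="session")
def dumbbell():
    return make_structure(FixtureSpec(kind="two_domain_dumbbell", seed=5))


def rigid_body_fields(coords):
    """Six (3N,) rigid-body displacement fields (3 translations, 3
    infinitesimal rotations about the centroid)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    fields = []
    for axis in np.eye(3):
        fields.append(np.tile(axis, n))
    centred = coords - coords.mean(axis=0)
    for axis in np.eye(3):
        fields.append(np.cross(axis, centred).ravel())
    return np.array(fields)
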