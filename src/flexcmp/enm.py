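"""Cα elastic network: pair potential, Hessian assembly, normal modes.

The network couples every pair of beads with a harmonic spring whose
stiffness depends on the pair's separation in the input configuration,

    k(r) = a*r - b   for r <  d,
    k(r) = c*r**-6   for r >= d,

with a = 8.6e5 kJ mol^-1 nm^-3, b = 2.39e5 kJ mol^-1 nm^-2,
c = 128 kJ mol^-1 nm^4 and d = 0.4 nm.  The short-range branch models the
stiff pseudo-bond between sequence neighbours (which sit just below
0.4 nm apart); the r^-6 decay localises all other interactions without a
hard cutoff.  The pair energy is k(r0)*(r - r0)^2, so the input
configuration is the energy minimum by construction.

Normal modes are eigenvectors of the mass-weighted Hessian
M^(-1/2) H M^(-1/2); the six zero eigenvalues of a connected
three-dimensional network are the rigid-body translations and rotations
and are excluded from every analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .errors import DisconnectedNetworkError
from .io import validate_min_distance
from .structures import CalphaStructure

#: Relative eigenvalue threshold below which a mode counts as trivial
#: (rigid body).  Relative to the largest eigenvalue.
TRIVIAL_MODE_TOL = 1e-9

#: Number of modes kept by default in the single-structure analyses.
DEFAULT_MODE_COUNT = 200


@dataclass(frozen=True)
class ForceFieldParams:
    """Parameters of the distance-dependent force constant.

    Units: ``a`` kJ mol^-1 nm^-3, ``b`` kJ mol^-1 nm^-2,
    ``c`` kJ mol^-1 nm^4, ``d`` (branch boundary) nm.
    """

    a: float = 8.6e5
    b: float = 2.39e5
    c: float = 128.0
    d: float = 0.4

    def __post_init__(self):
        if self.a * self.d - self.b <= 0:
            raise ValueError("a*d - b must be positive")
        if self.c <= 0 or self.d <= 0:
            raise ValueError("c and d must be positive")


def pair_force_constant(r, params: ForceFieldParams = ForceFieldParams()):
    """Distance-dependent spring stiffness k(r) in kJ mol^-1 nm^-2.

    ``r`` may be a scalar or array of distances in nm; all must be
    positive.  At the branch boundary r == d the long-range branch
    applies.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    return np.where(r < params.d, params.a * r - params.b, params.c * r ** -6)


@dataclass
class Hessian:
    """3N x 3N second-derivative matrix of the network energy at R0.

    ``matrix`` is symmetric positive semidefinite with units
    kJ mol^-1 nm^-2; ``spring_constants`` holds the (N, N) matrix of pair
    stiffnesses actually used (zero where a cutoff removed the pair),
    which downstream code reuses for per-pair energies and connectivity.
    """

    matrix: np.ndarray
    structure: CalphaStructure
    params: ForceFieldParams
    spring_constants: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.structure.n_residues


def build_hessian(
    structure: CalphaStructure,
    params: ForceFieldParams = ForceFieldParams(),
    cutoff: float | None = None,
) -> Hessian:
    """Assemble the analytic Hessian of the pair potential at R0.

    Every pair interacts by default (the r^-6 decay provides locality);
    ``cutoff`` (nm) optionally drops pairs beyond it for large systems.
    The structure is validated against the 0.278 nm minimum distance
    first; violations propagate.

    For each interacting pair the off-diagonal 3x3 block is
    -2*k(r0)*u*u^T with u the unit vector along the pair, and the
    diagonal blocks accumulate the opposite sign, which makes every
    row-block sum vanish (translation invariance).
    """
    validate_min_distance(structure)
    coords = structure.coordinates
    n = structure.n_residues
    dists = squareform(pdist(coords))
    np.fill_diagonal(dists, 1.0)  # placeholder, masked below
    k = pair_force_constant(dists, params)
    np.fill_diagonal(k, 0.0)
    if cutoff is not None:
        k[squareform(pdist(coords)) > cutoff] = 0.0
        np.fill_diagonal(k, 0.0)

    diff = coords[:, None, :] - coords[None, :, :]
    u = diff / dists[:, :, None]
    # (N, N, 3, 3) stiffness blocks 2*k*u*u^T
    blocks = 2.0 * k[:, :, None, None] * u[:, :, :, None] * u[:, :, None, :]
    h = -blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    diag = blocks.sum(axis=1)  # (N, 3, 3)
    for i in range(n):
        h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = diag[i]
    h = 0.5 * (h + h.T)
    return Hessian(matrix=h, structure=structure, params=params, spring_constants=k)


@dataclass
class ModeSet:
    """Eigen-decomposition of a mass-weighted Hessian.

    ``eigenvalues`` (ascending, kJ mol^-1 nm^-2 Da^-1) and ``vectors``
    (orthonormal columns of the mass-weighted eigenvectors) cover the
    retained non-trivial modes; the ``n_trivial`` near-zero rigid-body
    modes are kept separately for completeness checks.
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray  # (3N, M) mass-weighted, orthonormal
    masses: np.ndarray  # (N,) per-bead masses used for weighting
    n_trivial: int
    trivial_eigenvalues: np.ndarray = field(default=None)
    trivial_vectors: np.ndarray = field(default=None)

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.masses.shape[0]

    @property
    def cartesian_displacements(self) -> np.ndarray:
        """(3N, M) real-space displacement patterns M^(-1/2) X_m."""
        w = np.repeat(self.masses, 3)
        return self.vectors / np.sqrt(w)[:, None]

    def displacement(self, m: int) -> np.ndarray:
        """(N, 3) cartesian displacement field of retained mode ``m``."""
        return self.cartesian_displacements[:, m].reshape(-1, 3)


def mass_weighted_modes(
    matrix: np.ndarray,
    masses: np.ndarray,
    trivial_tol: float = TRIVIAL_MODE_TOL,
    adjacency: np.ndarray | None = None,
) -> ModeSet:
    """Diagonalise M^(-1/2) H M^(-1/2) and split off the trivial modes.

    Trivial (rigid-body) modes are the eigenvalues below
    ``trivial_tol`` times the largest eigenvalue.  More than six of them
    triggers a warning — or an error when ``adjacency`` (a boolean or
    stiffness matrix of the springs) shows the network is disconnected,
    since the extra zero modes are then independent rigid bodies.
    """
    matrix = np.asarray(matrix, dtype=float)
    masses = np.asarray(masses, dtype=float)
    w = np.repeat(masses, 3)
    inv_sqrt = 1.0 / np.sqrt(w)
    mw = matrix * np.outer(inv_sqrt, inv_sqrt)
    mw = 0.5 * (mw + mw.T)
    eigvals, eigvecs = scipy.linalg.eigh(mw)
    lam_max = float(eigvals[-1])
    if lam_max <= 0:
        raise ValueError("Hessian has no positive eigenvalue")
    n_trivial = int(np.count_nonzero(eigvals < trivial_tol * lam_max))
    if n_trivial > 6:
        if adjacency is not None:
            n_comp, _ = connected_components(
                np.asarray(adjacency) > 0, directed=False
            )
            if n_comp > 1:
                raise DisconnectedNetworkError(
                    f"spring network splits into {n_comp} components "
                    f"({n_trivial} near-zero modes)"
                )
        warnings.warn(
            f"{n_trivial} near-zero modes found (expected 6 for a connected "
            "3-D network)",
            stacklevel=2,
        )
    return ModeSet(
        eigenvalues=eigvals[n_trivial:],
        vectors=eigvecs[:, n_trivial:],
        masses=masses,
        n_trivial=n_trivial,
        trivial_eigenvalues=eigvals[:n_trivial],
        trivial_vectors=eigvecs[:, :n_trivial],
    )


def compute_modes(
    hessian: Hessian,
    masses: np.ndarray | None = None,
    trivial_tol: float = TRIVIAL_MODE_TOL,
) -> ModeSet:
    """Normal modes of a structure's Hessian.

    ``masses`` defaults to the structure's residue masses; pass an array
    of ones for uniform (geometric) weighting.
    """
    if masses is None:
        masses = hessian.structure.masses
    return mass_weighted_modes(
        hessian.matrix,
        masses,
        trivial_tol=trivial_tol,
        adjacency=hessian.spring_constants,
    )


def truncate_modes(modes: ModeSet, k: int = DEFAULT_MODE_COUNT) -> ModeSet:
    """Keep the min(k, available) lowest-frequency non-trivial modes."""
    if k < 1:
        raise ValueError("mode count must be >= 1")
    k = min(k, modes.n_modes)
    return ModeSet(
        eigenvalues=modes.eigenvalues[:k],
        vectors=modes.vectors[:, :k],
        masses=modes.masses,
        n_trivial=modes.n_trivial,
        trivial_eigenvalues=modes.trivial_eigenvalues,
        trivial_vectors=modes.trivial_vectors,
    )


def network_energy(
    structure: CalphaStructure,
    coords: np.ndarray,
    params: ForceFieldParams = ForceFieldParams(),
    cutoff: float | None = None,
) -> float:
    """Total elastic energy U of an arbitrary configuration ``coords``.

    Sum over pairs of k(r0_ij) * (r_ij - r0_ij)^2 with stiffness pinned
    at the reference geometry.  Mainly used by tests as a brute-force
    check on the analytic Hessian.
    """
    ref = structure.coordinates
    r0 = pdist(ref)
    r = pdist(np.asarray(coords, dtype=float))
    k = pair_force_constant(r0, params)
    if cutoff is not None:
        k = np.where(r0 > cutoff, 0.0, k)
    return float(np.sum(k * (r - r0) ** 2))
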