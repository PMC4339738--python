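"""Comparative analysis of aligned structure sets.

Maps alignment columns to residues, reduces each elastic network to the
alignment-conserved subsystem by a Schur complement, and compares the
resulting mode spaces pairwise with RMSIP and the Bhattacharyya
coefficient, with complete-linkage clustering of the similarity matrix.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .enm import (
    ForceFieldParams,
    Hessian,
    ModeSet,
    build_hessian,
    compute_modes,
    mass_weighted_modes,
)
from .errors import AlignmentMappingError, DegenerateInputError
from .single import deformation_energies, fluctuations
from .structures import CalphaStructure, GappedAlignment

#: Default variance fractions of the two-step rank reduction used by the
#: Bhattacharyya coefficient.
VAR_PROTEIN = 0.95
VAR_JOINT = 0.75

#: Number of low-frequency modes in the RMSIP subspaces.
RMSIP_MODES = 10


@dataclass
class AlignmentMap:
    """Correspondence between alignment columns and residue indices.

    ``column_to_residue[k]`` is an int array over alignment columns for
    structure ``k``: the 0-based residue index, or -1 at a gap.
    ``conserved_columns`` are the gap-free columns (0-based).
    """

    structure_ids: list
    column_to_residue: list
    conserved_columns: np.ndarray
    nonconserved_columns: np.ndarray

    @property
    def column_count(self) -> int:
        return len(self.column_to_residue[0])

    def conserved_residues(self, index: int) -> np.ndarray:
        """0-based residue indices of structure ``index`` at conserved columns."""
        return self.column_to_residue[index][self.conserved_columns]


def _sequences_match(aligned: str, structure_seq: str) -> int | None:
    """First mismatching position (0-based) or None; 'X' matches anything."""
    if len(aligned) != len(structure_seq):
        return min(len(aligned), len(structure_seq))
    for i, (a, b) in enumerate(zip(aligned, structure_seq)):
        if a != b and a != "X" and b != "X":
            return i
    return None


def map_alignment(
    alignment: GappedAlignment, structures: list
) -> AlignmentMap:
    """Check alignment/structure consistency and build the column maps.

    Records are matched to structures by order; each record's ungapped
    sequence must equal its structure's one-letter sequence ('X'
    wildcards allowed on either side).  A column is conserved when no
    record has a gap there.
    """
    if len(alignment.records) != len(structures):
        raise AlignmentMappingError(
            None,
            message=(
                f"{len(alignment.records)} alignment records but "
                f"{len(structures)} structures"
            ),
        )
    ncol = alignment.column_count
    col_maps = []
    for idx, ((name, gapped), structure) in enumerate(
        zip(alignment.records, structures)
    ):
        ungapped = gapped.replace("-", "")
        mismatch = _sequences_match(ungapped, structure.one_letter_sequence)
        if mismatch is not None:
            raise AlignmentMappingError(
                structure.structure_id, position=mismatch + 1
            )
        cmap = np.full(ncol, -1, dtype=int)
        res = 0
        for col, ch in enumerate(gapped):
            if ch != "-":
                cmap[col] = res
                res += 1
        col_maps.append(cmap)
    stacked = np.stack(col_maps)
    conserved = np.flatnonzero((stacked >= 0).all(axis=0))
    if conserved.size == 0:
        raise AlignmentMappingError(
            None, message="no gap-free (conserved) columns in the alignment"
        )
    nonconserved = np.setdiff1d(np.arange(ncol), conserved)
    return AlignmentMap(
        structure_ids=[s.structure_id for s in structures],
        column_to_residue=col_maps,
        conserved_columns=conserved,
        nonconserved_columns=nonconserved,
    )


@dataclass
class ReducedModeSet:
    """Modes of the alignment-conserved subsystem of one structure.

    ``conserved_coordinates`` keeps the conserved beads' positions so
    pairwise comparisons can superpose the two systems into a common
    frame before comparing mode vectors.
    """

    structure_id: str
    effective_hessian: np.ndarray  # (3|a|, 3|a|)
    modes: ModeSet
    conserved_residues: np.ndarray  # 0-based indices into the full structure
    conserved_coordinates: np.ndarray = None  # (|a|, 3) nm


def schur_complement(matrix: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Exact reduction of a quadratic form to the coordinates ``keep``.

    Returns H_aa - H_ab H_bb^-1 H_ab^T, the curvature of the energy
    after minimising over the complementary coordinates: for any x_a,
    (1/2) x_a^T Hred x_a equals min over x_b of the full quadratic
    energy.  A singular complementary block falls back to a
    pseudo-inverse with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    keep = np.asarray(keep, dtype=int)
    drop = np.setdiff1d(np.arange(matrix.shape[0]), keep)
    if drop.size == 0:
        reduced = matrix.copy()
    else:
        h_aa = matrix[np.ix_(keep, keep)]
        h_ab = matrix[np.ix_(keep, drop)]
        h_bb = matrix[np.ix_(drop, drop)]
        try:
            y = scipy.linalg.solve(h_bb, h_ab.T, assume_a="sym")
        except scipy.linalg.LinAlgError:
            warnings.warn(
                "singular complementary block; using a pseudo-inverse",
                stacklevel=2,
            )
            y = scipy.linalg.pinvh(h_bb) @ h_ab.T
        reduced = h_aa - h_ab @ y
    return 0.5 * (reduced + reduced.T)


def effective_hessian(
    hessian: Hessian, amap: AlignmentMap, structure_index: int
) -> ReducedModeSet:
    """Reduce a Hessian to the alignment-conserved residues.

    The conserved residues' 3 coordinates each form the kept block; the
    Schur complement over the rest preserves the full network's
    flexibility rather than just the sub-block's.  Modes of the reduced
    matrix are mass-weighted with the conserved residues' masses.
    """
    a_res = amap.conserved_residues(structure_index)
    a_idx = (3 * a_res[:, None] + np.arange(3)).ravel()
    reduced = schur_complement(hessian.matrix, a_idx)
    masses = hessian.structure.masses[a_res]
    modes = mass_weighted_modes(reduced, masses)
    return ReducedModeSet(
        structure_id=hessian.structure.structure_id,
        effective_hessian=reduced,
        modes=modes,
        conserved_residues=a_res,
        conserved_coordinates=hessian.structure.coordinates[a_res],
    )


@dataclass
class ProfileTable:
    """Per-alignment-column profile values, one column per structure.

    Backed by a DataFrame indexed by 1-based alignment column; NaN marks
    gaps and is written as an empty field.
    """

    data: pd.DataFrame
    kind: str  # "fluctuation" or "deformation"


def aligned_profiles(
    structures: list,
    amap: AlignmentMap,
    mode_sets: list,
    params: ForceFieldParams = ForceFieldParams(),
    normalization: str = "sum_to_one",
):
    """Fluctuation and deformation profiles tabulated on alignment columns.

    Profiles are computed per structure from its full (unreduced) mode
    set over all non-trivial modes, then placed at that structure's
    alignment columns; gap positions stay blank.  Returns
    ``(fluctuation_table, deformation_table)``.
    """
    ncol = amap.column_count
    index = np.arange(1, ncol + 1)
    fluct = pd.DataFrame(np.nan, index=index, columns=amap.structure_ids)
    deform = pd.DataFrame(np.nan, index=index, columns=amap.structure_ids)
    for idx, (structure, modes) in enumerate(zip(structures, mode_sets)):
        f = fluctuations(modes, normalization=normalization).values
        e = deformation_energies(
            modes, structure, params, normalization=normalization
        ).values
        cmap = amap.column_to_residue[idx]
        present = cmap >= 0
        cols = np.flatnonzero(present)
        fluct.iloc[cols, idx] = f[cmap[present]]
        deform.iloc[cols, idx] = e[cmap[present]]
    fluct.index.name = "alignment_column"
    deform.index.name = "alignment_column"
    return (
        ProfileTable(data=fluct, kind="fluctuation"),
        ProfileTable(data=deform, kind="deformation"),
    )


def _comparison_vectors(
    red: ReducedModeSet, mass_weighted: bool, rotation: np.ndarray | None = None
) -> np.ndarray:
    vecs = red.modes.vectors if mass_weighted else red.modes.cartesian_displacements
    vecs = vecs / np.linalg.norm(vecs, axis=0)
    if rotation is not None:
        n = vecs.shape[0] // 3
        vecs = (
            (vecs.T.reshape(-1, n, 3) @ rotation.T)
            .reshape(-1, 3 * n)
            .T
        )
    return vecs


def _frame_rotation(red_a: ReducedModeSet, red_b: ReducedModeSet):
    """Rotation carrying B's frame onto A's, from superposing the
    conserved coordinates.  Mode-vector comparisons are meaningless
    across frames, so every pairwise measure applies this first."""
    if red_a.conserved_coordinates is None or red_b.conserved_coordinates is None:
        return None
    from .single import kabsch_rotation

    return kabsch_rotation(red_b.conserved_coordinates, red_a.conserved_coordinates)


def rmsip(
    red_a: ReducedModeSet,
    red_b: ReducedModeSet,
    n_modes: int = RMSIP_MODES,
    mass_weighted: bool = False,
) -> float:
    """Root mean squared inner product of the two low-mode subspaces.

    sqrt( (1/n) sum_{i,j<=n} (X_i . Y_j)^2 ) over the n lowest-frequency
    non-trivial modes (n = 10 by convention), with unit-normalised
    displacement vectors, after superposing B's conserved coordinates
    onto A's.  Compares subspace directions only, ignoring the
    eigenvalue spectrum.
    """
    if red_a.modes.vectors.shape[0] != red_b.modes.vectors.shape[0]:
        raise ValueError("reduced systems have different dimensions")
    avail = min(red_a.modes.n_modes, red_b.modes.n_modes)
    if avail < n_modes:
        warnings.warn(
            f"only {avail} non-trivial modes available; RMSIP uses all of them",
            stacklevel=2,
        )
        n_modes = avail
    rot = _frame_rotation(red_a, red_b)
    x = _comparison_vectors(red_a, mass_weighted)[:, :n_modes]
    y = _comparison_vectors(red_b, mass_weighted, rotation=rot)[:, :n_modes]
    return float(np.sqrt(np.sum((x.T @ y) ** 2) / n_modes))


@dataclass
class ReducedCovariance:
    """Intermediate quantities of the two-step BC rank reduction."""

    n: int  # modes kept for protein A (95% variance)
    m: int  # modes kept for protein B
    a_n: np.ndarray  # trace-normalised covariance of A
    b_m: np.ndarray
    s: int  # joint projection dimension (75% variance)
    a_tilde: np.ndarray  # s x s projected covariances
    b_tilde: np.ndarray


def _mode_covariance(
    red: ReducedModeSet,
    var_fraction: float,
    mass_weighted: bool,
    rotation: np.ndarray | None = None,
    min_modes: int = 1,
):
    """Trace-normalised covariance from the softest modes covering
    ``var_fraction`` of the total 1/lambda variance (at least
    ``min_modes``); returns (cov, n)."""
    lam = red.modes.eigenvalues
    weights = 1.0 / lam
    cum = np.cumsum(weights)
    n = int(np.searchsorted(cum, var_fraction * cum[-1] - 1e-12) + 1)
    n = min(max(n, min_modes), lam.size)
    d = red.modes.vectors if mass_weighted else red.modes.cartesian_displacements
    if rotation is not None:
        n_atoms = d.shape[0] // 3
        d = (d.T.reshape(-1, n_atoms, 3) @ rotation.T).reshape(-1, 3 * n_atoms).T
    d = d[:, :n]
    cov = (d * weights[:n]) @ d.T
    return cov / np.trace(cov), n


def reduce_covariances(
    red_a: ReducedModeSet,
    red_b: ReducedModeSet,
    var_protein: float = VAR_PROTEIN,
    var_joint: float = VAR_JOINT,
    mass_weighted: bool = False,
) -> ReducedCovariance:
    """Build the rank-reduced covariance pair the BC is evaluated on.

    Per protein, the covariance sum_m (1/lambda_m) d_m d_m^T is built
    from the fewest lowest-frequency modes retaining ``var_protein`` of
    the variance and normalised to unit trace; both matrices are then
    projected onto the ``s`` leading eigenvectors of their average that
    retain ``var_joint`` of its variance.
    """
    if red_a.modes.vectors.shape[0] != red_b.modes.vectors.shape[0]:
        raise ValueError("reduced systems have different dimensions")
    rot = _frame_rotation(red_a, red_b)
    # the projected covariances must have full rank s, so the per-protein
    # mode counts are floored at s and the projection recomputed until
    # consistent (keeping >= var_protein of the variance throughout)
    min_modes = 1
    while True:
        a_cov, n = _mode_covariance(
            red_a, var_protein, mass_weighted, min_modes=min_modes
        )
        b_cov, m = _mode_covariance(
            red_b, var_protein, mass_weighted, rotation=rot,
            min_modes=min_modes,
        )
        avg = 0.5 * (a_cov + b_cov)
        eigvals, eigvecs = scipy.linalg.eigh(avg)
        eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
        cum = np.cumsum(eigvals)
        s = int(np.searchsorted(cum, var_joint * cum[-1] - 1e-12) + 1)
        max_avail = min(red_a.modes.n_modes, red_b.modes.n_modes)
        if s <= min(n, m) or min_modes >= max_avail:
            break
        min_modes = min(s, max_avail)
    v = eigvecs[:, :s]
    return ReducedCovariance(
        n=n,
        m=m,
        a_n=a_cov,
        b_m=b_cov,
        s=s,
        a_tilde=v.T @ a_cov @ v,
        b_tilde=v.T @ b_cov @ v,
    )


def _logdet_pd(matrix: np.ndarray, name: str) -> float:
    eigvals = scipy.linalg.eigvalsh(matrix)
    if eigvals.min() <= 0:
        raise DegenerateInputError(
            f"projected covariance {name} is not positive definite "
            "(numerically degenerate input)"
        )
    return float(np.sum(np.log(eigvals)))


def bhattacharyya(
    red_a: ReducedModeSet,
    red_b: ReducedModeSet,
    var_protein: float = VAR_PROTEIN,
    var_joint: float = VAR_JOINT,
    mass_weighted: bool = False,
) -> float:
    """Bhattacharyya coefficient between two mode covariances, in (0, 1].

    BC = exp( -(1/2s) ln[ |(A~+B~)/2| / sqrt(|A~| |B~|) ] ) on the
    rank-reduced covariances; 1 means the Gaussian ensembles implied by
    the two mode sets coincide.  Unlike RMSIP it weighs directions by
    their variance, so it is sensitive to the eigenvalue spectrum too.
    Determinants are evaluated in log space to avoid underflow.
    """
    rc = reduce_covariances(
        red_a, red_b, var_protein=var_protein, var_joint=var_joint,
        mass_weighted=mass_weighted,
    )
    log_avg = _logdet_pd(0.5 * (rc.a_tilde + rc.b_tilde), "(A+B)/2")
    log_a = _logdet_pd(rc.a_tilde, "A")
    log_b = _logdet_pd(rc.b_tilde, "B")
    return float(np.exp(-(log_avg - 0.5 * (log_a + log_b)) / (2 * rc.s)))


@dataclass
class SimilarityMatrix:
    """Pairwise similarity values with a complete-linkage dendrogram."""

    labels: list
    values: np.ndarray
    measure: str  # "RMSIP" or "BC"
    linkage_matrix: np.ndarray

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels from cutting the dendrogram."""
        return fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")


def similarity_matrix(
    reduced: list, measure: str = "BC", **kwargs
) -> SimilarityMatrix:
    """All-pairs RMSIP or BC with complete-linkage clustering.

    The dendrogram is built on the dissimilarity 1 - value; the matrix
    keeps input order (self-comparisons on the diagonal).
    """
    if len(reduced) < 2:
        raise ValueError("at least 2 structures are required")
    measure = measure.upper()
    if measure == "RMSIP":
        func = rmsip
    elif measure == "BC":
        func = bhattacharyya
    else:
        raise ValueError(f"unknown similarity measure '{measure}'")
    k = len(reduced)
    values = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = func(reduced[i], reduced[j], **kwargs)
    dist = np.clip(1.0 - values, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="complete")
    return SimilarityMatrix(
        labels=[r.structure_id for r in reduced],
        values=values,
        measure=measure,
        linkage_matrix=link,
    )


def comparative_pipeline(
    structures: list,
    alignment: GappedAlignment,
    params: ForceFieldParams = ForceFieldParams(),
    var_protein: float = VAR_PROTEIN,
    var_joint: float = VAR_JOINT,
):
    """Run the full comparative analysis on validated inputs.

    Returns a dict with the alignment map, full and reduced mode sets,
    the two aligned profile tables and the RMSIP and BC similarity
    matrices.
    """
    amap = map_alignment(alignment, structures)
    hessians = [build_hessian(s, params) for s in structures]
    full_modes = [compute_modes(h) for h in hessians]
    fluct_table, deform_table = aligned_profiles(
        structures, amap, full_modes, params
    )
    reduced = [
        effective_hessian(h, amap, i) for i, h in enumerate(hessians)
    ]
    return {
        "alignment_map": amap,
        "full_modes": full_modes,
        "reduced": reduced,
        "fluctuations": fluct_table,
        "deformation": deform_table,
        "rmsip": similarity_matrix(reduced, "RMSIP"),
        "bc": similarity_matrix(
            reduced, "BC", var_protein=var_protein, var_joint=var_joint
        ),
    }
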