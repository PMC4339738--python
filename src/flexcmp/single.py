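"""Single-structure analyses.

Fluctuation and deformation-energy profiles, the inter-residue
correlation matrix with PyMOL export, and the overlap of the modes with
an observed conformational change.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .enm import DEFAULT_MODE_COUNT, ForceFieldParams, ModeSet, pair_force_constant
from .errors import DegenerateInputError
from .structures import CalphaStructure

#: Pairs closer than this (nm) are excluded from the correlation viewer
#: script: sequence-local contacts are dominated by the stiff backbone
#: springs and would drown the long-range couplings of interest.
VIEWER_MIN_DISTANCE_NM = 0.8


def _normalize(values: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "sum_to_one":
        total = values.sum()
    elif normalization == "max_to_one":
        total = values.max()
    else:
        raise ValueError(f"unknown normalization '{normalization}'")
    if total <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return values / total


@dataclass
class FluctuationProfile:
    """Normalised per-residue mean-square displacement amplitudes."""

    values: np.ndarray
    normalization: str = "sum_to_one"


@dataclass
class DeformationProfile:
    """Normalised per-residue share of the elastic deformation energy."""

    values: np.ndarray
    normalization: str = "sum_to_one"


@dataclass
class CorrelationMatrix:
    """Inter-residue displacement correlations C_ij in [-1, 1]."""

    C: np.ndarray
    n_modes_used: int


@dataclass
class OverlapResult:
    """Projection of a conformational difference onto the mode basis."""

    squared_overlaps: np.ndarray  # O_m per retained mode
    cumulative: np.ndarray  # CO_k = sqrt(sum_{m<=k} O_m)
    delta: np.ndarray  # superposed coordinate difference, flattened (3N,)


def _require_modes(modes: ModeSet):
    if modes.n_modes < 1:
        raise ValueError("at least one non-trivial mode is required")


def fluctuations(
    modes: ModeSet, normalization: str = "sum_to_one"
) -> FluctuationProfile:
    """Per-residue fluctuation profile.

    Each retained mode contributes its squared per-atom cartesian
    displacement weighted by the reciprocal eigenvalue (soft modes move
    most); the profile is then normalised (sum to one by default).
    """
    _require_modes(modes)
    d = modes.cartesian_displacements.reshape(modes.n_atoms, 3, modes.n_modes)
    raw = np.einsum("icm,icm,m->i", d, d, 1.0 / modes.eigenvalues)
    return FluctuationProfile(
        values=_normalize(raw, normalization), normalization=normalization
    )


def per_atom_deformation(
    structure: CalphaStructure,
    params: ForceFieldParams,
    displacement: np.ndarray,
    spring_constants: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom elastic energy of one displacement field, (N,) array.

    Each pair's harmonic energy k(r0)*(u_hat . (d_i - d_j))^2 — the
    second-order energy of the pair potential — is split half-and-half
    between its two partners.  Rigid-body fields cost nothing.
    """
    coords = structure.coordinates
    n = structure.n_residues
    disp = np.asarray(displacement, dtype=float).reshape(n, 3)
    dists = squareform(pdist(coords))
    np.fill_diagonal(dists, 1.0)
    if spring_constants is None:
        k = pair_force_constant(dists, params)
        np.fill_diagonal(k, 0.0)
    else:
        k = spring_constants
    u = (coords[:, None, :] - coords[None, :, :]) / dists[:, :, None]
    proj = np.einsum("ijc,ic->ij", u, disp) - np.einsum("ijc,jc->ij", u, disp)
    pair_energy = k * proj**2
    return 0.5 * pair_energy.sum(axis=1)


def deformation_energies(
    modes: ModeSet,
    structure: CalphaStructure,
    params: ForceFieldParams = ForceFieldParams(),
    normalization: str = "sum_to_one",
) -> DeformationProfile:
    """Per-residue deformation-energy profile over the retained modes.

    Mode contributions are weighted by 1/lambda like the fluctuations,
    so the soft modes that dominate thermal motion also dominate the
    profile; hinge residues between rigid domains stand out as maxima.
    """
    _require_modes(modes)
    coords = structure.coordinates
    n = structure.n_residues
    dists = squareform(pdist(coords))
    np.fill_diagonal(dists, 1.0)
    k = pair_force_constant(dists, params)
    np.fill_diagonal(k, 0.0)
    u = (coords[:, None, :] - coords[None, :, :]) / dists[:, :, None]
    d = modes.cartesian_displacements.reshape(n, 3, modes.n_modes)
    proj = np.einsum("ijc,icm->ijm", u, d) - np.einsum("ijc,jcm->ijm", u, d)
    pair_energy = k[:, :, None] * proj**2
    raw = 0.5 * np.einsum("ijm,m->i", pair_energy, 1.0 / modes.eigenvalues)
    return DeformationProfile(
        values=_normalize(raw, normalization), normalization=normalization
    )


def correlation_matrix(
    modes: ModeSet, max_modes: int = DEFAULT_MODE_COUNT
) -> CorrelationMatrix:
    """Normalised cross-correlations of residue displacements.

    C_ij is the 1/lambda-weighted inner product of the displacement
    vectors of residues i and j over the retained modes, normalised by
    the per-residue amplitudes; it is the expected inner product of
    displacements and ranges from -1 (anti-correlated) to 1.
    """
    _require_modes(modes)
    m = min(max_modes, modes.n_modes)
    d = modes.cartesian_displacements[:, :m].reshape(modes.n_atoms, 3, m)
    g = np.einsum("icm,jcm,m->ij", d, d, 1.0 / modes.eigenvalues[:m])
    amp = np.sqrt(np.diag(g))
    c = g / np.outer(amp, amp)
    return CorrelationMatrix(C=c, n_modes_used=m)


def viewer_percentile(n_residues: int) -> float:
    """Percentile used to threshold |C_ij| in the viewer export.

    95 below 200 residues, 99.9 above 2000, linear in N between — the
    quadratic growth of the number of pairs calls for a stricter
    threshold on larger structures.
    """
    if n_residues < 200:
        return 95.0
    if n_residues > 2000:
        return 99.9
    return 95.0 + (99.9 - 95.0) * (n_residues - 200) / (2000 - 200)


def select_correlated_pairs(
    c: CorrelationMatrix,
    structure: CalphaStructure,
    percentile: float | None = None,
    min_distance: float = VIEWER_MIN_DISTANCE_NM,
):
    """Pick the significantly correlated long-range residue pairs.

    Only pairs at least ``min_distance`` nm apart in the reference
    structure are eligible; the threshold is the given percentile of
    |C_ij| over those pairs.  Returns
    ``(percentile, threshold, positive_pairs, negative_pairs)`` with
    0-based index pairs.
    """
    n = structure.n_residues
    if c.C.shape[0] != n:
        raise ValueError("correlation matrix and structure sizes differ")
    if percentile is None:
        percentile = viewer_percentile(n)
    dists = squareform(pdist(structure.coordinates))
    iu, ju = np.triu_indices(n, k=1)
    eligible = dists[iu, ju] >= min_distance
    iu, ju = iu[eligible], ju[eligible]
    if iu.size == 0:
        return percentile, np.nan, [], []
    vals = c.C[iu, ju]
    threshold = float(np.percentile(np.abs(vals), percentile))
    pos = [(int(i), int(j)) for i, j, v in zip(iu, ju, vals) if v > threshold]
    neg = [(int(i), int(j)) for i, j, v in zip(iu, ju, vals) if v < -threshold]
    return percentile, threshold, pos, neg


def correlation_viewer_script(
    c: CorrelationMatrix,
    structure: CalphaStructure,
    percentile: float | None = None,
    min_distance: float = VIEWER_MIN_DISTANCE_NM,
) -> str:
    """PyMOL script drawing significant correlations on the structure.

    Positive correlations above the threshold become red dashes/sticks,
    negatives below its negation blue; the percentile and threshold are
    recorded as header comments.  An empty selection still yields a
    valid script.
    """
    percentile, threshold, pos, neg = select_correlated_pairs(
        c, structure, percentile=percentile, min_distance=min_distance
    )
    labels = structure.residue_labels
    lines = [
        "# flexcmp correlation viewer script",
        f"# structure: {structure.structure_id}",
        f"# n_residues: {structure.n_residues}",
        f"# modes_used: {c.n_modes_used}",
        f"# percentile: {percentile:.4g}",
        f"# threshold: {threshold:.6g}",
        f"# min_pair_distance_nm: {min_distance}",
        "hide everything",
        "show cartoon",
        "color grey80",
    ]

    def atom_sel(idx: int) -> str:
        chain, resnum, icode, _ = labels[idx]
        return f"chain {chain} and resi {resnum}{icode} and name CA"

    for name, color, pairs in (("poscorr", "red", pos), ("negcorr", "blue", neg)):
        for i, j in pairs:
            lines.append(f"distance {name}, ({atom_sel(i)}), ({atom_sel(j)})")
        if pairs:
            lines.append(f"color {color}, {name}")
            lines.append(f"hide labels, {name}")
    if pos or neg:
        lines.append("set dash_gap, 0")
        lines.append("set dash_radius, 0.15")
    return "\n".join(lines) + "\n"


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal (proper) rotation matrix aligning centred ``mobile`` onto
    centred ``reference`` in the least-squares sense."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    u, _, vt = np.linalg.svd(mob_c.T @ ref_c)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    return (u @ d @ vt).T


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``.

    Returns the transformed copy of ``mobile``; both are (N, 3) arrays.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    rot = kabsch_rotation(mobile, reference)
    return (mobile - mobile.mean(axis=0)) @ rot.T + reference.mean(axis=0)


def overlap_analysis(
    modes: ModeSet,
    structure_a: CalphaStructure,
    structure_b: CalphaStructure,
) -> OverlapResult:
    """How well the modes of conformation A span the change A → B.

    B is first superposed onto A (removing the rigid-body difference the
    modes cannot represent); the normalised squared projection of the
    remaining difference onto each retained mode's displacement pattern
    is the squared overlap O_m, and CO_k = sqrt(sum of the first k) the
    cumulative overlap.
    """
    _require_modes(modes)
    if structure_a.n_residues != structure_b.n_residues:
        raise ValueError(
            "the two conformations have different residue counts "
            f"({structure_a.n_residues} vs {structure_b.n_residues})"
        )
    if structure_a.one_letter_sequence != structure_b.one_letter_sequence:
        raise ValueError("the two conformations have different sequences")
    b_fit = superpose(structure_b.coordinates, structure_a.coordinates)
    delta = (b_fit - structure_a.coordinates).ravel()
    norm = np.linalg.norm(delta)
    if norm < 1e-8:
        raise DegenerateInputError(
            "the two conformations are identical after superposition"
        )
    d = modes.cartesian_displacements
    proj = d.T @ delta
    overlaps = proj**2 / (np.sum(d**2, axis=0) * norm**2)
    return OverlapResult(
        squared_overlaps=overlaps,
        cumulative=np.sqrt(np.cumsum(overlaps)),
        delta=delta,
    )
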