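"""Synthetic test structures, families and conformational pairs.

Everything here is generated, seeded and self-contained: ideal Cα
helices, compact self-avoiding random blobs, two-domain dumbbells with a
flexible linker, noisy structure families with a consistent gapped
alignment, and open/closed conformational pairs produced by a hinge
rotation.  These stand in for downloaded PDB entries in tests and demos;
they are geometrically valid elastic networks, not realistic protein
decoys.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .errors import FlexcmpError
from .structures import CalphaStructure, GappedAlignment, residue_mass

#: Consecutive-Cα spacing (nm) of real protein backbones.
CA_STEP_NM = 0.38
#: Clash limit used during generation, slightly above the 0.278 nm
#: validation bound so fixtures always pass validation.
CLASH_NM = 0.30

HELIX_RISE_NM = 0.15
HELIX_RADIUS_NM = 0.23
HELIX_TWIST_DEG = 100.0

DUMBBELL_DOMAIN = 12
DUMBBELL_LINKER = 4

_MAX_RESTARTS = 200


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic input.

    ``kind`` is one of {"helix", "compact_blob", "two_domain_dumbbell",
    "family", "open_closed_pair"}; ``noise_sigma`` is the coordinate
    noise in nm for family members; ``count`` the number of copies.
    """

    kind: str
    n_residues: int = 20
    noise_sigma: float = 0.0
    seed: int = 0
    count: int = 1

    def __post_init__(self):
        if self.n_residues < 5:
            raise ValueError("fixtures need at least 5 residues")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")


def _polyala(structure_id: str, coords: np.ndarray) -> CalphaStructure:
    n = coords.shape[0]
    labels = [("A", i + 1, "", "ALA") for i in range(n)]
    masses = np.full(n, residue_mass("A"))
    return CalphaStructure(
        structure_id=structure_id,
        residue_labels=labels,
        coordinates=coords,
        masses=masses,
    )


def _helix_coords(n: int) -> np.ndarray:
    t = np.arange(n) * np.deg2rad(HELIX_TWIST_DEG)
    return np.column_stack(
        [
            HELIX_RADIUS_NM * np.cos(t),
            HELIX_RADIUS_NM * np.sin(t),
            HELIX_RISE_NM * np.arange(n),
        ]
    )


def _blob_coords(n: int, rng: np.random.Generator, origin=(0.0, 0.0, 0.0)):
    """Compact self-avoiding walk: 0.38 nm steps biased toward the
    centroid, restarted whenever a bead cannot be placed clash-free."""
    origin = np.asarray(origin, dtype=float)
    for _ in range(_MAX_RESTARTS):
        coords = [origin]
        failed = False
        for _ in range(n - 1):
            centroid = np.mean(coords, axis=0)
            placed = False
            for _ in range(100):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pull = centroid - coords[-1]
                pull_norm = np.linalg.norm(pull)
                if pull_norm > 1e-9:
                    direction = direction + 0.7 * pull / pull_norm
                    direction /= np.linalg.norm(direction)
                candidate = coords[-1] + CA_STEP_NM * direction
                dists = cdist([candidate], coords)[0]
                if dists.min() >= CLASH_NM:
                    coords.append(candidate)
                    placed = True
                    break
            if not placed:
                failed = True
                break
        if not failed:
            return np.array(coords)
    raise FlexcmpError(f"could not generate a clash-free {n}-bead blob")


def _dumbbell_coords(
    rng: np.random.Generator,
    n_domain: int = DUMBBELL_DOMAIN,
    n_linker: int = DUMBBELL_LINKER,
):
    """Two compact domains joined by an extended linker along +x.

    Returns ``(coords, hinge_slice)`` where ``hinge_slice`` marks the
    linker beads.
    """
    # zig-zag step pattern of an ideal extended strand: a perfectly
    # straight linker would be a zero-energy mechanism for central-force
    # springs (free transverse motion), which no real backbone is
    zig = np.array([0.33, 0.19, 0.0])
    zag = np.array([0.33, -0.19, 0.0])
    for _ in range(_MAX_RESTARTS):
        dom_a = _blob_coords(n_domain, rng)
        # attach the linker to the domain bead with the largest x
        start = dom_a[np.argmax(dom_a[:, 0])]
        steps = [zig if i % 2 == 0 else zag for i in range(n_linker)]
        linker = start + np.cumsum(steps, axis=0)
        anchor = linker[-1] + (zig if n_linker % 2 == 0 else zag)
        dom_b = _blob_coords(n_domain, rng, origin=anchor)
        coords = np.vstack([dom_a, linker, dom_b])
        if pdist(coords).min() >= CLASH_NM:
            hinge = slice(n_domain, n_domain + n_linker)
            return coords, hinge
    raise FlexcmpError("could not generate a clash-free dumbbell")


def make_structure(spec: FixtureSpec) -> CalphaStructure:
    """Generate one synthetic poly-alanine Cα structure.

    Helices use 0.15 nm rise, 0.23 nm radius and 100 degrees per residue
    (consecutive beads then sit 0.38 nm apart as in real backbones);
    blobs are compact self-avoiding walks; dumbbells are two 12-bead
    blobs joined by a 4-bead extended linker (``n_residues`` ignored for
    the dumbbell default geometry).  Same spec, same output.
    """
    rng = np.random.default_rng(spec.seed)
    sid = f"{spec.kind}_{spec.seed}"
    if spec.kind == "helix":
        coords = _helix_coords(spec.n_residues)
    elif spec.kind == "compact_blob":
        coords = _blob_coords(spec.n_residues, rng)
    elif spec.kind == "two_domain_dumbbell":
        coords, _ = _dumbbell_coords(rng)
    else:
        raise ValueError(f"make_structure cannot build kind '{spec.kind}'")
    if spec.noise_sigma > 0:
        coords = _perturb(coords, spec.noise_sigma, rng)
    return _polyala(sid, coords)


def _perturb(coords: np.ndarray, sigma: float, rng: np.random.Generator):
    for _ in range(_MAX_RESTARTS):
        noisy = coords + rng.normal(scale=sigma, size=coords.shape)
        if pdist(noisy).min() >= CLASH_NM:
            return noisy
    raise FlexcmpError("could not generate a clash-free noisy copy")


def _delete_residues(coords: np.ndarray, start: int, length: int):
    keep = np.ones(coords.shape[0], dtype=bool)
    keep[start : start + length] = False
    return coords[keep]


def make_family(
    spec: FixtureSpec,
    base_kind: str = "compact_blob",
    indels: bool = False,
    family_id: str | None = None,
):
    """Noisy copies of one base fold plus a consistent gapped alignment.

    Each copy perturbs the family's base fold by seeded Gaussian
    coordinate noise of ``spec.noise_sigma`` nm (re-sampled until
    clash-free).  With ``indels`` every second copy loses a short
    interior stretch, producing gap columns.  Returns
    ``(structures, alignment)``.
    """
    if spec.count < 2:
        raise ValueError("a family needs count >= 2")
    rng = np.random.default_rng(spec.seed)
    fid = family_id or f"fam{spec.seed}"
    base = _blob_coords(spec.n_residues, rng) if base_kind == "compact_blob" \
        else _helix_coords(spec.n_residues)
    structures = []
    records = []
    n = spec.n_residues
    for c in range(spec.count):
        coords = _perturb(base, spec.noise_sigma, rng) \
            if spec.noise_sigma > 0 else base.copy()
        gapped = ["A"] * n
        if indels and c % 2 == 1:
            start = int(rng.integers(2, n - 5))
            length = int(rng.integers(1, 4))
            coords = _delete_residues(coords, start, length)
            for p in range(start, start + length):
                gapped[p] = "-"
        sid = f"{fid}_copy{c}"
        structures.append(_polyala(sid, coords))
        records.append((sid, "".join(gapped)))
    return structures, GappedAlignment(records=records)


def make_family_set(specs: list, base_kind: str = "compact_blob", indels=False):
    """Several families merged into one structure list and alignment.

    Families may differ in length; shorter records are padded with
    trailing gaps so all rows share the longest family's column count.
    """
    all_structures = []
    all_records = []
    for f, spec in enumerate(specs):
        structures, aln = make_family(
            spec, base_kind=base_kind, indels=indels, family_id=f"fam{f}"
        )
        all_structures.extend(structures)
        all_records.extend(aln.records)
    ncol = max(len(seq) for _, seq in all_records)
    padded = [(name, seq + "-" * (ncol - len(seq))) for name, seq in all_records]
    return all_structures, GappedAlignment(records=padded)


def make_open_closed_pair(
    spec: FixtureSpec, angle_deg: float = 30.0
):
    """Open/closed conformations of a dumbbell related by a hinge bend.

    The 'closed' copy rotates the second domain (and trailing half of
    the linker) about an axis through the linker midpoint, re-sampling
    the dumbbell if the rotation produces a clash.  Both conformers
    share the same residue labels and sequence.
    """
    rng = np.random.default_rng(spec.seed)
    for attempt in range(_MAX_RESTARTS):
        coords, hinge = _dumbbell_coords(rng)
        pivot_index = (hinge.start + hinge.stop) // 2
        pivot = coords[pivot_index]
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * np.array([0.0, 0.0, 1.0]))
        closed = coords.copy()
        moving = slice(pivot_index, coords.shape[0])
        closed[moving] = rot.apply(closed[moving] - pivot) + pivot
        if angle_deg == 0 or pdist(closed).min() >= CLASH_NM:
            open_structure = _polyala(f"open_{spec.seed}", coords)
            closed_structure = _polyala(f"closed_{spec.seed}", closed)
            return open_structure, closed_structure
    raise FlexcmpError("could not generate a clash-free closed conformation")


def make(spec: FixtureSpec):
    """Dispatch on ``spec.kind`` for the CLI."""
    if spec.kind in ("helix", "compact_blob", "two_domain_dumbbell"):
        return [make_structure(spec)], None
    if spec.kind == "family":
        half = max(2, spec.count // 2)
        specs = [
            replace(spec, count=half, seed=spec.seed),
            replace(spec, count=half, seed=spec.seed + 1),
        ]
        return make_family_set(specs)
    if spec.kind == "open_closed_pair":
        return list(make_open_closed_pair(spec)), None
    raise ValueError(f"unknown fixture kind '{spec.kind}'")
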