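"""Reading and writing the formats the tool touches.

PDB files are parsed with biotite (first model, highest-occupancy
alternate locations); gapped alignments with biotite's FASTA reader.
All numeric result files are plain tab-separated text.
"""
from __future__ import annotations

import os
import warnings as _warnings

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence.io.fasta import FastaFile
from scipy.spatial.distance import pdist

from .errors import AlignmentFormatError, MinimumDistanceError, PDBFormatError
from .structures import (
    GAP_CHARS,
    THREE_TO_ONE,
    CalphaStructure,
    GappedAlignment,
    residue_mass,
)

#: Smallest Cα–Cα distance (nm) at which the force field is attractive;
#: below it the a·r − b branch turns negative (b/a ≈ 0.278 nm), so closer
#: pairs are rejected before any computation.
MIN_CA_DISTANCE_NM = 0.278

ANGSTROM_PER_NM = 10.0

_NUM_FMT = "%.17g"  # round-trips doubles exactly


def read_pdb_calpha(path, chains=None, structure_id=None) -> CalphaStructure:
    """Extract one Cα bead per residue from a PDB file.

    Only the first MODEL is used; for alternate locations the highest
    occupancy wins (ties: first in file).  MSE (selenomethionine) HETATM
    records are treated as methionine; all other HETATM records are
    skipped with a warning recorded on the returned structure.

    Parameters
    ----------
    path : str or Path
        PDB-format text file.
    chains : iterable of str, optional
        Chain identifiers to keep; default: all chains.
    structure_id : str, optional
        Label for the structure; default: the file's base name.
    """
    if structure_id is None:
        structure_id = os.path.splitext(os.path.basename(str(path)))[0]
    try:
        pdb_file = PDBFile.read(str(path))
        atoms = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:
        raise PDBFormatError(f"cannot parse PDB file '{path}': {exc}") from exc

    if chains is not None:
        chains = set(chains)
        atoms = atoms[np.isin(atoms.chain_id, sorted(chains))]

    parse_warnings = []
    hetero_skipped = atoms.hetero & (atoms.res_name != "MSE")
    if np.any(hetero_skipped):
        skipped_names = sorted(set(atoms.res_name[hetero_skipped]))
        parse_warnings.append(
            "ignored heteroatom residue(s): " + ", ".join(skipped_names)
        )
    atoms = atoms[~hetero_skipped]

    is_ca = atoms.atom_name == "CA"
    ca = atoms[is_ca]
    if ca.array_length() < 2:
        raise PDBFormatError(
            f"fewer than 2 C-alpha atoms found in '{path}'"
            + (f" (chains {sorted(chains)})" if chains else "")
        )

    labels = []
    seen = set()
    nonstandard = set()
    for i in range(ca.array_length()):
        name = str(ca.res_name[i]).upper()
        label = (
            str(ca.chain_id[i]),
            int(ca.res_id[i]),
            str(ca.ins_code[i]).strip(),
            name,
        )
        key = label[:3]
        if key in seen:
            raise PDBFormatError(
                f"duplicate residue {key} after alternate-location resolution"
            )
        seen.add(key)
        if name not in THREE_TO_ONE:
            nonstandard.add(name)
        labels.append(label)
    if nonstandard:
        parse_warnings.append(
            "non-standard residue(s) mapped to 'X': "
            + ", ".join(sorted(nonstandard))
        )

    # biotite stores float32; recover the file's 3-decimal values before
    # converting so coordinates are clean in float64
    coords_nm = np.round(np.asarray(ca.coord, dtype=float), 3) / ANGSTROM_PER_NM
    seq = "".join(THREE_TO_ONE.get(lab[3], "X") for lab in labels)
    masses = np.array([residue_mass(c) for c in seq])
    return CalphaStructure(
        structure_id=structure_id,
        residue_labels=labels,
        coordinates=coords_nm,
        masses=masses,
        warnings=parse_warnings,
    )


def write_pdb(structure: CalphaStructure, path) -> None:
    """Write the Cα beads back out as a minimal PDB file (coordinates in Å)."""
    n = structure.n_residues
    arr = struc.AtomArray(n)
    arr.coord = structure.coordinates * ANGSTROM_PER_NM
    arr.chain_id = np.array([lab[0] for lab in structure.residue_labels])
    arr.res_id = np.array([lab[1] for lab in structure.residue_labels])
    arr.ins_code = np.array([lab[2] for lab in structure.residue_labels])
    res_names = []
    for lab in structure.residue_labels:
        res_names.append(lab[3])
    arr.res_name = np.array(res_names)
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    pdb_file = PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def validate_min_distance(structure: CalphaStructure) -> None:
    """Reject structures with a Cα pair closer than 0.278 nm (2.78 Å).

    The bound is where the short-range branch of the force constant turns
    negative, i.e. where the elastic network would no longer be at a
    potential minimum.  The comparison is strict: a pair at exactly
    0.278 nm passes.
    """
    coords = structure.coordinates
    d = pdist(coords)
    if d.size and d.min() < MIN_CA_DISTANCE_NM:
        n = structure.n_residues
        iu, ju = np.triu_indices(n, k=1)
        k = int(np.flatnonzero(d < MIN_CA_DISTANCE_NM)[0])
        raise MinimumDistanceError((iu[k] + 1, ju[k] + 1), d[k])


def read_alignment(path) -> GappedAlignment:
    """Read a gapped FASTA multiple alignment.

    Both '-' and '.' are accepted as gap characters; sequences are
    upper-cased.  Raises on ragged alignments or fewer than 2 records.
    """
    try:
        fasta = FastaFile.read(str(path))
    except Exception as exc:
        raise AlignmentFormatError(
            f"cannot parse FASTA file '{path}': {exc}"
        ) from exc
    records = []
    for name, seq in fasta.items():
        seq = seq.upper()
        for gap in GAP_CHARS[1:]:
            seq = seq.replace(gap, "-")
        records.append((name, seq))
    return GappedAlignment(records=records)


def write_alignment(alignment: GappedAlignment, path) -> None:
    fasta = FastaFile()
    for name, seq in alignment.records:
        fasta[name] = seq
    fasta.write(str(path))


def _write_lines(path, header_lines, lines):
    with open(path, "w") as fh:
        for line in header_lines or ():
            fh.write(f"# {line}\n")
        for line in lines:
            fh.write(line + "\n")


def write_profile_table(table, path, header_lines=None) -> None:
    """Write an alignment-indexed profile table as tab-separated text.

    Rows are alignment columns; one column per structure; fields are
    empty at gap positions.
    """
    df = table.data
    lines = ["alignment_column\t" + "\t".join(str(c) for c in df.columns)]
    for idx, row in zip(df.index, df.to_numpy()):
        fields = [
            "" if not np.isfinite(v) else _NUM_FMT % v for v in row
        ]
        lines.append(str(idx) + "\t" + "\t".join(fields))
    _write_lines(path, header_lines, lines)


def write_matrix(matrix, path, header_lines=None) -> None:
    """Write a labelled square matrix (similarity or correlation) as TSV.

    ``matrix`` needs ``values`` (2-D array) and optionally ``labels``;
    correlation matrices fall back to 1-based residue indices.
    """
    values = np.asarray(matrix.values if hasattr(matrix, "values") else matrix.C)
    labels = getattr(matrix, "labels", None)
    if labels is None:
        labels = [str(i + 1) for i in range(values.shape[0])]
    lines = ["\t" + "\t".join(labels)]
    for lab, row in zip(labels, values):
        lines.append(lab + "\t" + "\t".join(_NUM_FMT % v for v in row))
    _write_lines(path, header_lines, lines)


def read_matrix(path):
    """Read back a matrix written by :func:`write_matrix`.

    Returns ``(labels, values)``.
    """
    labels = None
    rows = []
    row_labels = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if labels is None:
                labels = fields[1:]
                continue
            row_labels.append(fields[0])
            rows.append([float(x) for x in fields[1:]])
    if labels is None:
        raise ValueError(f"no matrix content in '{path}'")
    return row_labels, np.array(rows)


def write_modes(modes, path, header_lines=None) -> None:
    """Write eigenvalues and mass-weighted eigenvectors as text.

    One row per retained (non-trivial) mode: the eigenvalue followed by
    the 3N components of the mass-weighted eigenvector.
    """
    lines = []
    for m in range(modes.n_modes):
        vals = [modes.eigenvalues[m]] + list(modes.vectors[:, m])
        lines.append("\t".join(_NUM_FMT % v for v in vals))
    _write_lines(path, header_lines, lines)
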