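"""In-memory containers for coarse-grained structures and gapped alignments.

A protein is represented by one bead per residue, placed at the Cα
position.  Coordinates are stored in nanometres throughout the package;
the Ångström convention of the PDB format is converted away at the I/O
boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentFormatError

#: Three-letter → one-letter code for the 20 standard amino acids.
#: Selenomethionine (MSE) is read as methionine.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

#: Average residue masses in Da (amino acid minus one water), the scale at
#: which a one-bead-per-residue model operates.  Unknown residues ('X')
#: receive the table mean.
RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
MEAN_RESIDUE_MASS = float(np.mean(list(RESIDUE_MASSES.values())))

#: Characters treated as alignment gaps on input.
GAP_CHARS = ("-", ".")


def residue_mass(one_letter: str) -> float:
    """Mass in Da for a one-letter residue code ('X' → table mean)."""
    return RESIDUE_MASSES.get(one_letter, MEAN_RESIDUE_MASS)


@dataclass
class CalphaStructure:
    """One-bead-per-residue protein model (the reference configuration).

    Parameters
    ----------
    structure_id : str
        Short label, typically derived from the file name.
    residue_labels : list of (chain_id, residue_number, insertion_code,
        residue_name) tuples, in bead order.
    coordinates : (N, 3) ndarray
        Cα positions in nm.
    masses : (N,) ndarray
        Per-residue masses in Da.
    warnings : list of str
        Parse-time notices (skipped heteroatoms, non-standard residues).
    """

    structure_id: str
    residue_labels: list
    coordinates: np.ndarray
    masses: np.ndarray
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.residue_labels)
        if n < 2:
            raise ValueError("a structure needs at least 2 residues")
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{n} residue labels"
            )
        if self.masses.shape != (n,):
            raise ValueError("masses length does not match residue count")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise ValueError("non-positive residue mass")

    @property
    def n_residues(self) -> int:
        return len(self.residue_labels)

    @property
    def one_letter_sequence(self) -> str:
        return "".join(
            THREE_TO_ONE.get(lab[3].upper(), "X") for lab in self.residue_labels
        )

    def with_coordinates(self, coordinates: np.ndarray) -> "CalphaStructure":
        """Copy of this structure with replaced coordinates (same labels)."""
        return CalphaStructure(
            structure_id=self.structure_id,
            residue_labels=list(self.residue_labels),
            coordinates=np.asarray(coordinates, dtype=float),
            masses=self.masses.copy(),
            warnings=list(self.warnings),
        )


@dataclass
class GappedAlignment:
    """Multiple sequence alignment with gaps, as read from gapped FASTA.

    ``records`` is an ordered list of ``(name, gapped_sequence)`` pairs;
    sequences are upper-case with '-' as the only gap character ('.' is
    normalised to '-' on input).
    """

    records: list

    def __post_init__(self):
        if len(self.records) < 2:
            raise AlignmentFormatError("an alignment needs at least 2 records")
        lengths = {len(seq) for _, seq in self.records}
        if 0 in lengths:
            raise AlignmentFormatError("empty alignment record")
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"ragged alignment: record lengths {sorted(lengths)} differ"
            )

    @property
    def column_count(self) -> int:
        return len(self.records[0][1])

    @property
    def names(self):
        return [name for name, _ in self.records]

    def ungapped(self, index: int) -> str:
        """Sequence of record ``index`` with gap characters removed."""
        return self.records[index][1].replace("-", "")
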