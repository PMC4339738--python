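"""Exception hierarchy.

The CLI maps these onto distinct exit codes, so keep parse / validation /
mapping failures as separate branches.
"""


class FlexcmpError(Exception):
    """Base class for all errors raised by flexcmp."""


class PDBFormatError(FlexcmpError):
    """The structure file could not be parsed into Cα beads."""


class AlignmentFormatError(FlexcmpError):
    """The FASTA alignment is malformed (ragged, empty, too few records)."""


class MinimumDistanceError(FlexcmpError):
    """Two Cα atoms are closer than the 0.278 nm force-field minimum.

    Attributes
    ----------
    pair : tuple of int
        1-based residue indices of the first offending pair.
    distance : float
        Their separation in nm.
    """

    def __init__(self, pair, distance):
        self.pair = tuple(pair)
        self.distance = float(distance)
        super().__init__(
            f"C-alpha atoms {self.pair[0]} and {self.pair[1]} are "
            f"{self.distance:.4f} nm apart, closer than the 0.278 nm "
            f"minimum distance supported by the force field"
        )


class AlignmentMappingError(FlexcmpError):
    """A gapped alignment record does not match its structure's sequence."""

    def __init__(self, structure_id, position=None, message=None):
        self.structure_id = structure_id
        self.position = position
        if message is None:
            message = (
                f"alignment record for '{structure_id}' does not match the "
                f"structure sequence (first mismatch at position {position})"
            )
        super().__init__(message)


class DisconnectedNetworkError(FlexcmpError):
    """The spring network splits into independent components."""


class DegenerateInputError(FlexcmpError):
    """Input is numerically degenerate (e.g. identical conformations)."""
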