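"""Exception hierarchy.

All cppkit errors derive from :class:`CppkitError` so callers can catch the
package's failures with a single ``except`` clause while still being able to
distinguish malformed input from modelling problems.
"""

from __future__ import annotations


class CppkitError(Exception):
    """Base class for all cppkit exceptions."""


class SequenceError(CppkitError):
    """A peptide sequence violates the natural-residue contract."""


class NonCanonicalResidueError(SequenceError):
    """Sequence contains characters outside the 20 canonical amino acids.

    Parameters
    ----------
    offending : list of (position, character) pairs, 1-based positions.
    """

    def __init__(self, sequence: str, offending: list[tuple[int, str]]):
        self.sequence = sequence
        self.offending = offending
        where = ", ".join(f"'{c}' at position {i}" for i, c in offending)
        super().__init__(f"non-canonical residues in {sequence!r}: {where}")


class TooShortError(SequenceError):
    """Sequence shorter than the 3-residue minimum."""

    def __init__(self, sequence: str):
        self.sequence = sequence
        super().__init__(
            f"sequence {sequence!r} has length {len(sequence)} < 3; "
            "at least one tripeptide window is required"
        )


class DuplicateIdError(CppkitError):
    """Two records share the same identifier."""


class MissingLabelError(CppkitError):
    """A peptide id present in the FASTA is absent from the label sidecar."""


class ColumnMismatchError(CppkitError):
    """Feature-matrix columns disagree in name, order or count."""


class UnknownHeaderError(CppkitError):
    """A tabular file does not follow the expected header layout."""


class SingleClassError(CppkitError):
    """An operation requiring both classes received only one."""


class EmptySampleError(CppkitError):
    """A statistical test received an empty sample."""


class TooFewPerClassError(CppkitError):
    """Cross-validation requested more folds than the smallest class size."""


class LengthMismatchError(CppkitError):
    """Aligned vectors (truth/predictions/rows) have different lengths."""


class UnmappedFeatureError(CppkitError):
    """A feature name cannot be assigned to a descriptor block."""


class MissingFeatureError(CppkitError):
    """A required feature column is absent from the matrix."""


class VersionMismatchError(CppkitError):
    """A model bundle was written by an unknown format version."""


class HashMismatchError(CppkitError):
    """A model bundle's manifest and serialized state disagree."""
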