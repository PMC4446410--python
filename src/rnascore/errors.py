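"""Exception hierarchy for rnascore."""


class RnascoreError(Exception):
    """Base class for all rnascore errors."""


class EmptyStructureError(RnascoreError):
    """A PDB stream contained no parseable nucleotide atoms."""


class MissingModelError(RnascoreError):
    """The requested MODEL index is absent from a multi-model file."""


class UnknownAtomTypeError(RnascoreError, KeyError):
    """(residue code, atom name) pair is not one of the 85 canonical types."""


class DegenerateGeometryError(RnascoreError):
    """Collinear or coincident points make a torsion angle undefined."""


class InsufficientCorrespondenceError(RnascoreError):
    """Fewer than three matched atoms available for superposition."""


class UndefinedReferenceError(RnascoreError):
    """The reference interaction set is empty, so INF is undefined."""


class ModelFileError(RnascoreError):
    """A potential parameter file is unreadable (bad version, truncated, or corrupt)."""
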