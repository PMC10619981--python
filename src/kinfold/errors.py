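"""Exception hierarchy shared by all kinfold stages."""


class KinfoldError(Exception):
    """Base class for all package-specific errors."""


class EmptyStructureError(KinfoldError):
    """A coordinate file or model contained no atoms."""


class FormatError(KinfoldError):
    """A value cannot be represented in the requested file format."""


class DegenerateGeometryError(KinfoldError):
    """Too few or collinear points for a rigid-body fit."""


class SiteLookupError(KinfoldError, KeyError):
    """A (chain, residue, atom) site is absent from the model."""


class SchemaError(KinfoldError):
    """A tabular input is missing a required column."""


class ParseError(KinfoldError):
    """A tabular input row could not be interpreted."""


class EmptyReportError(KinfoldError):
    """A validation report was requested for zero crosslinks."""


class InsufficientOverlapError(KinfoldError):
    """Fewer than three shared residues between two fragments."""


class UnderConstrainedError(KinfoldError):
    """Fewer than three restraints connect a fragment to the assembly."""


class AssemblyError(KinfoldError):
    """A fragment can be neither stitched nor placed."""
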