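"""Exception hierarchy for the EET pipeline."""


class EETError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(EETError):
    """The structural model file could not be read or is malformed."""


class ExtractionError(EETError):
    """A pigment residue could not be turned into a valid Pigment."""


class DomainError(EETError):
    """Domain assignment failed (unmapped chain, unknown domain id, ...)."""


class GeometryError(EETError):
    """Degenerate or clashing geometry (coincident centers, atom clash)."""


class ChargeSetError(EETError):
    """A transition-charge table is invalid or cannot be applied."""


class LineshapeError(EETError):
    """Invalid lineshape/overlap parameters."""


class RateError(EETError):
    """Invalid inputs to a rate computation (negative overlap, T ≤ 0 K)."""


class NetworkError(EETError):
    """Invalid network-analysis inputs (unsorted bins, unknown domain)."""
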