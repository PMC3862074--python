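"""Exception hierarchy shared across the package."""


class HRVError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HRVError):
    """A tachogram file could not be parsed (carries the offending line number)."""


class EmptyInputError(HRVError):
    """An input file or sequence contained no usable data."""


class UnusableRecordError(HRVError):
    """Every beat of a record was flagged; no NN series can be built."""


class InsufficientDataError(HRVError):
    """A segment is too short for the requested index."""


class CoverageError(HRVError):
    """A requested clock window is not covered by the recording."""


class DegenerateCloudError(HRVError):
    """The Poincare cloud collapsed onto a line or point (SD1 or SD2 is zero)."""


class RatioUndefinedError(HRVError):
    """A spectral band ratio has a zero denominator."""


class ContractError(HRVError):
    """An operation was called with inputs violating its documented contract."""


class InfeasibleCompositionError(HRVError):
    """The candidate pool cannot supply the requested index-set composition."""
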