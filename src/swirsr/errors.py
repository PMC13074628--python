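"""Exception hierarchy shared across the package."""


class SwirsrError(Exception):
    """Base class for all package-specific errors."""


class MissingConstantError(SwirsrError, KeyError):
    """A requested wavelength has no tabulated constant (no silent interpolation)."""


class DomainError(SwirsrError, ValueError):
    """An argument is outside its physically meaningful domain."""


class ParseError(SwirsrError, ValueError):
    """A tabular input file violates the expected schema."""


class LowSNRError(SwirsrError, ValueError):
    """A measurement yielded a non-positive signal and is excluded from inversion."""


class ReferenceInvalidError(SwirsrError, ValueError):
    """The reference (PTFE) signal is non-positive; normalization undefined."""


class OutOfRangeError(SwirsrError, ValueError):
    """A corrected ratio falls outside the lookup-table range (no extrapolation)."""


class MonotonicityError(SwirsrError, ValueError):
    """A ratio curve is non-monotonic beyond statistical tolerance."""


class PipelineError(SwirsrError, RuntimeError):
    """The end-to-end inversion could not produce an estimate; reasons attached."""

    def __init__(self, message: str, reasons: dict | None = None):
        super().__init__(message)
        self.reasons = reasons or {}
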