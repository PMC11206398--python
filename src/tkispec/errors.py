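"""Exception hierarchy shared across the package."""


class TkispecError(Exception):
    """Base class for all package errors."""


class ParseError(TkispecError):
    """A file could not be parsed (malformed XYZ, stick table or manifest)."""


class ValidationError(TkispecError):
    """A value violates a domain invariant (negative f, bad element, ...)."""


class NoQualifyingTransitionError(TkispecError):
    """No excited state satisfies the oscillator-strength rule.

    Raised by :func:`tkispec.spectra.lambda_max` instead of silently falling
    back to a weaker transition.
    """


class GridMismatchError(TkispecError):
    """Two spectra do not share an identical wavelength grid."""


class DegenerateGeometryError(TkispecError):
    """A point set is collinear or otherwise unusable for superposition."""


class PipelineError(TkispecError):
    """One or more compounds failed inside the end-to-end pipeline."""

    def __init__(self, message: str, failures: dict[str, str] | None = None):
        super().__init__(message)
        self.failures = failures or {}
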