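"""Exception hierarchy for the package."""


class MCFMKMError(Exception):
    """Base class for all package-specific errors."""


class DegenerateSpectrumError(MCFMKMError):
    """Raised when a spectrum carries no positive dose-probability mass."""


class GridRangeError(MCFMKMError):
    """Raised when a lineal energy falls outside the span of the binning grid."""


class SpectrumParseError(MCFMKMError):
    """Raised on malformed spectrum files; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UnknownSpeciesError(MCFMKMError):
    """Raised when a species has no built-in DNA-content/karyotype constants."""


class InconsistentParametersError(MCFMKMError):
    """Raised when a photon dose-response set cannot yield a physical parameter,
    e.g. when beta0 * z_d(yD_ref) exceeds alpha_ref so alpha0 would be negative."""


class ConfigError(MCFMKMError):
    """Raised on over-, under-, or mis-specified cell-line configurations."""
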