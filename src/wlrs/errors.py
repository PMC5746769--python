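"""Exception hierarchy for the WLRS workbench.

Every error raised by the package derives from :class:`WLRSError` so callers
(and the CLI) can map failure categories to exit codes.
"""


class WLRSError(Exception):
    """Base class for all package errors."""


class InvalidInputError(WLRSError, ValueError):
    """A function argument violates its documented precondition."""


class GridMismatchError(InvalidInputError):
    """Two spectra that must share a wavelength grid do not."""


class DegenerateReferenceError(WLRSError):
    """REF(λ) − D(λ) is non-positive somewhere in the working range."""

    def __init__(self, wavelength_nm: float):
        self.wavelength_nm = wavelength_nm
        super().__init__(
            f"reference minus dark is non-positive at {wavelength_nm:.3f} nm; "
            "normalization undefined"
        )


class TrackingError(WLRSError):
    """Peak tracking lost the extremum (zero or multiple candidates)."""

    def __init__(self, time_s: float, n_found: int):
        self.time_s = time_s
        self.n_found = n_found
        super().__init__(
            f"peak tracking failed at t={time_s:g} s: "
            f"{n_found} extrema in window (expected exactly 1)"
        )


class NonConvergenceError(WLRSError):
    """An optimisation did not converge within its iteration budget."""


class ConfigError(WLRSError):
    """A run configuration file is malformed or contains unknown keys."""


class SpectrumFormatError(WLRSError):
    """A spectrum file on disk is malformed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
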