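"""Exception hierarchy shared across the package."""


class MeltkinError(Exception):
    """Base class for all package-specific errors."""


class TraceFormatError(MeltkinError):
    """A trace file does not conform to the delimited-text dialect."""


class TraceDataError(MeltkinError):
    """A trace violates a data invariant (ordering, length, range)."""


class FitError(MeltkinError):
    """A nonlinear fit failed to converge.

    Carries the best residual diagnostics seen across starts, if any.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(MeltkinError):
    """An analysis configuration is invalid."""
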