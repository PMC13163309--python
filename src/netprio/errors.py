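"""Exception hierarchy shared across the pipeline stages."""


class NetprioError(Exception):
    """Base class for all package errors."""


class ConfigError(NetprioError):
    """Invalid configuration value; message names the offending field."""


class ValidationError(NetprioError):
    """Malformed or out-of-range input data."""


class FixtureError(NetprioError):
    """Packaged fixture missing or failing its integrity check."""


class FitError(NetprioError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
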