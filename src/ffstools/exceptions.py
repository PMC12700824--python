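"""Exception hierarchy used across the package."""


class FFSToolsError(Exception):
    """Base class for all package errors."""


class ValidationError(FFSToolsError, ValueError):
    """Invalid parameter or configuration value."""


class SizeError(FFSToolsError, ValueError):
    """Requested simulation or array size exceeds platform limits."""


class ParseError(FFSToolsError, ValueError):
    """Malformed input file; message names the offending line/offset."""


class FitError(FFSToolsError, RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class TruncationError(FFSToolsError, ValueError):
    """Count range too small to hold the required probability mass."""


class UndeterminedError(FFSToolsError, ValueError):
    """Quantity not determined by the data (e.g. signal at background level)."""
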