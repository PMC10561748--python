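"""Exception hierarchy.

All library errors derive from :class:`CareshiftError` so callers (and the
CLI) can catch one base class.  Parameter/parse problems are ``ValueError``
flavoured; analysis failures (flagged trials) are ``RuntimeError`` flavoured
and carry enough context to be reported as structured diagnostics.
"""


class CareshiftError(Exception):
    """Base class for all careshift errors."""


class ParameterError(CareshiftError, ValueError):
    """Invalid user-supplied parameter (dimensions, indices, durations)."""


class DomainError(CareshiftError, ValueError):
    """Mathematical domain violation (e.g. non-positive gap length)."""


class ParseError(CareshiftError, ValueError):
    """Malformed input file; message names the offending row/column."""


class ConfigError(CareshiftError, ValueError):
    """Invalid or unknown configuration key/value."""


class AnalysisError(CareshiftError, RuntimeError):
    """An analysis step could not produce a valid index for this trial."""


class WindowError(AnalysisError):
    """An evaluation window is truncated or cannot be placed."""


class FitError(AnalysisError):
    """Curve fit did not converge or was rejected (e.g. at a bound)."""

    def __init__(self, message, fit=None):
        super().__init__(message)
        self.fit = fit


class ContactError(AnalysisError):
    """No seat contact could be detected in the force-plate stream."""


class PeakError(AnalysisError):
    """Too few velocity peaks found in the head-marker stream."""
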