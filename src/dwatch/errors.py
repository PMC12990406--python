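"""Exception hierarchy for the dwatch pipeline."""


class DwatchError(Exception):
    """Base class for all dwatch errors."""


class ParameterError(DwatchError, ValueError):
    """A kinetic or acquisition parameter is out of its valid range."""


class ConfigurationError(DwatchError, ValueError):
    """A configuration object or file is inconsistent."""


class CoverageError(DwatchError, ValueError):
    """An input trace or stream does not cover the requested window."""


class StreamParseError(DwatchError, ValueError):
    """A scan-stream file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyStreamError(DwatchError, ValueError):
    """An operation that needs scans received an empty stream."""


class FitError(DwatchError, RuntimeError):
    """Nonlinear fitting failed to converge; carries the best attempt."""

    def __init__(self, message: str, best=None):
        self.best = best
        super().__init__(message)


class NoSafeEndpointError(DwatchError, RuntimeError):
    """No time in the acquisition window satisfies the safety constraint."""
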