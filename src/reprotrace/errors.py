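"""Exception hierarchy for the reprotrace pipeline.

All package errors derive from :class:`ReprotraceError` so callers (and the
CLI) can distinguish data/configuration problems from programming bugs.
"""


class ReprotraceError(Exception):
    """Base class for all errors raised by reprotrace."""


class ConfigurationError(ReprotraceError):
    """A simulation or pipeline configuration is invalid."""


class ParameterError(ReprotraceError):
    """An operation received an out-of-range parameter."""


class SelectorError(ReprotraceError):
    """A sample/gene selector matched nothing or required samples are absent."""


class InputError(ReprotraceError):
    """Input data are malformed, empty, or inconsistent."""


class ParseError(InputError):
    """A file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class PlacementError(ReprotraceError):
    """Requested non-overlapping colony placement could not be satisfied."""


class TraceQualityError(ReprotraceError):
    """Control/edited traces disagree upstream of the cut after calibration."""
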