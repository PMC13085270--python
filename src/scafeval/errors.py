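"""Exception hierarchy shared across the toolkit."""


class ScafevalError(Exception):
    """Base class for all toolkit errors."""


class LayoutError(ScafevalError):
    """A genome layout violates a structural invariant."""


class ParseError(ScafevalError):
    """An input file could not be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class MetricError(ScafevalError):
    """Metric preconditions not met (e.g. empty shared contig set)."""
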