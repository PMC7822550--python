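"""Exception hierarchy shared across the package."""


class StreamriskError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(StreamriskError, ValueError):
    """Invalid input values (out-of-range frequencies, bad genotype counts, ...)."""


class RangeError(StreamriskError, ValueError):
    """An age falls outside the span covered by a rate table."""


class EvaluationError(StreamriskError, RuntimeError):
    """A discrimination statistic cannot be computed (degenerate scores,
    perfect separation, stratum without cases, ...)."""
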