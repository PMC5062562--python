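"""Exception hierarchy for the quadarray pipeline.

All validation failures raise a subclass of :class:`QuadArrayError` so callers
(and the CLI) can distinguish bad input (exit code 2) from I/O trouble
(exit code 3).
"""


class QuadArrayError(Exception):
    """Base class for all quadarray-specific errors."""


class FormatError(QuadArrayError, ValueError):
    """A file does not conform to the expected tabular dialect."""


class IntegrityError(QuadArrayError, ValueError):
    """Structurally valid input violates a data invariant
    (e.g. a probe printed more than four times, duplicated replicate index)."""


class DegenerateArrayError(QuadArrayError, ValueError):
    """An array whose signal distribution cannot be normalized
    (non-positive reference percentile)."""


class MissingSampleError(QuadArrayError, KeyError):
    """A requested (subset, experiment, strain) sample is absent."""


class AggregationError(QuadArrayError, ValueError):
    """Summaries for mismatched comparisons cannot be aggregated."""
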