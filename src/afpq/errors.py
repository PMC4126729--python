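"""Exception hierarchy.

Validation errors (bad inputs, malformed files, impossible configs) are kept
distinct from computation errors so the CLI can map them to exit codes 2 and
3 respectively.
"""


class AfpqError(Exception):
    """Base class for all package errors."""


class ValidationError(AfpqError, ValueError):
    """Invalid user input: bad parameters, malformed files, bad config."""


class ComputationError(AfpqError, RuntimeError):
    """A metric could not be computed from otherwise valid input."""


class DegenerateSeriesError(ComputationError):
    """A scaling regression has no usable spread (e.g. constant box counts)."""
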