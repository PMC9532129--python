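"""Exception hierarchy for metamarker.

All errors raised by the library derive from :class:`MetamarkerError` so
callers (and the CLI) can map them onto exit codes uniformly.
"""


class MetamarkerError(Exception):
    """Base class for all metamarker errors."""


class ValidationError(MetamarkerError):
    """A configuration or input value violates a documented invariant."""


class FormatError(MetamarkerError):
    """A file does not conform to the expected dialect."""


class EmptyJoinError(MetamarkerError):
    """Joining two inputs produced an empty result (no overlapping keys)."""


class DuplicateGeneError(MetamarkerError):
    """A gene identifier occurs more than once in an expression matrix."""


class LookupError_(MetamarkerError):
    """A requested gene or sample is absent."""


class ConfoundingError(MetamarkerError):
    """Batch labels are perfectly confounded with the biological grouping."""


class DomainError(MetamarkerError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class InsufficientDataError(MetamarkerError):
    """Too few studies, samples, or groups for the requested computation."""


class InfiniteEffectError(MetamarkerError):
    """An effect size is unbounded (zero pooled SD with unequal means, |r| = 1)."""
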