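"""Exception hierarchy shared across the package."""


class PloidymcError(Exception):
    """Base class for all package errors."""


class ParseError(PloidymcError):
    """A text input (idxstats, count table, BLAST table) is malformed."""


class SchemaError(PloidymcError):
    """Input parsed but does not satisfy the expected schema
    (e.g. a canonical chromosome is missing)."""


class ValidationError(PloidymcError):
    """A constructed object violates its invariants
    (zero-depth sample, missing metadata, bad configuration)."""


class DomainError(PloidymcError):
    """A mathematically invalid argument (zero marginal sum,
    probability outside [0, 1], ...)."""


class InvalidStateError(PloidymcError):
    """A model state for which the target density is undefined rather
    than zero — e.g. a sample whose every ploidy entry is 0 while it
    has reads: the multinomial cell probabilities do not exist there.
    Distinct from a -inf log density, which is a legal (always
    rejected) value."""


class ConvergenceError(PloidymcError):
    """Multi-chain diagnostics indicate the sampler has not converged."""
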