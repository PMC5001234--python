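"""Exception types used across the package."""


class EMSError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EMSError, ValueError):
    """Input data (sequence, motif, alphabet) violates a precondition."""


class InvalidParameterError(EMSError, ValueError):
    """Problem parameters (l, d, k, workers, ...) are inconsistent."""


class ContractViolationError(EMSError, RuntimeError):
    """An internal data-structure contract (sortedness, uniqueness) was broken."""


class CandidateLimitError(EMSError, RuntimeError):
    """The per-string compact candidate count exceeded the configured cap."""
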