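"""Exception types shared across the toolkit."""


class NanoselectError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NanoselectError, ValueError):
    """An argument violates an operation's preconditions."""


class DegenerateSignalError(NanoselectError):
    """A signal has zero spread and cannot be normalized.

    Callers that iterate over reads are expected to catch this, skip the
    read, and count the skip rather than abort.
    """


class DatasetImbalanceError(NanoselectError):
    """A training or evaluation set is missing one of the two classes."""
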