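"""Exception hierarchy shared across the package."""


class SquigsegError(Exception):
    """Base class for all package errors."""


class FormatError(SquigsegError):
    """A file does not conform to the expected dialect."""


class ValidationError(SquigsegError):
    """An input violates a documented precondition or invariant."""


class InsufficientCoverageError(ValidationError):
    """Too few observations to fit or call."""


class UnstandardizableReadError(ValidationError):
    """The read has no usable poly(A) interval for standardization."""
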