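"""Exception types shared across the package."""


class WavefbnError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(WavefbnError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(WavefbnError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. constant)."""


class TooShortSignalError(InvalidArgumentError):
    """A time series is too short for the requested operation."""


class AliasingError(InvalidArgumentError):
    """An analysis frequency exceeds the Nyquist limit."""


class AlignmentError(WavefbnError, ValueError):
    """Subject rows of two feature blocks do not line up."""
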