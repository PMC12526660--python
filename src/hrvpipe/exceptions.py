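"""Exception hierarchy shared across the pipeline."""


class HrvPipeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HrvPipeError, ValueError):
    """A parameter violates its documented precondition."""


class InsufficientDataError(HrvPipeError, ValueError):
    """Not enough samples/peaks/intervals to compute the quantity."""


class FormatError(HrvPipeError, ValueError):
    """A file could not be parsed in the declared format."""


class ValidationError(HrvPipeError, ValueError):
    """A composite input (reference table, config) is inconsistent."""
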