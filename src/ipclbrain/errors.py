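"""Exception hierarchy shared across the package."""


class IPCLBrainError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IPCLBrainError):
    """Invalid configuration (bad dimensions, unknown names, bad ranges)."""


class InputError(IPCLBrainError):
    """Invalid runtime input (empty sets, mismatched shapes, bad values)."""


class NumericError(IPCLBrainError):
    """Non-finite values or numerically undefined quantities."""


class DegeneratePrototypeError(NumericError):
    """Views cancel: their mean has (numerically) zero norm."""


class DegenerateTestError(NumericError):
    """A statistical test is undefined for the given data."""


class TrainingError(IPCLBrainError):
    """Divergence or other failure inside a training loop."""


class AlignmentError(InputError):
    """Condition or layer labels do not line up across objects."""


class CacheInvalidError(IPCLBrainError):
    """An activation cache does not match the requested model/images."""
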