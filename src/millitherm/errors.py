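"""Exception and warning types shared across the package."""


class MillithermError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MillithermError, ValueError):
    """An input lies outside the physical or mathematical domain of an operation."""


class DataError(MillithermError):
    """Malformed or unreadable input data."""


class IntegrityError(DataError):
    """A packaged fixture does not match its recorded checksum."""


class ConvergenceError(MillithermError, RuntimeError):
    """An iterative solver failed to converge."""


class NonIdentifiabilityWarning(UserWarning):
    """The data carry too little signal to pin down the model parameters."""


class ExtrapolationWarning(UserWarning):
    """A lookup was answered by extrapolating outside the tabulated range."""
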