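"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors -> 2 (click's own),
:class:`DataError` -> 3, :class:`NumericalError` -> 4.
"""


class PigmentNoiseError(Exception):
    """Base class for all package errors."""


class DomainError(PigmentNoiseError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DataError(PigmentNoiseError, ValueError):
    """Malformed, inconsistent or unusable input data."""


class DegenerateSignalError(DataError):
    """A signal carries no usable information (zero variance, all-zero waveform)."""


class NumericalError(PigmentNoiseError, RuntimeError):
    """A numerical procedure failed to converge or produced invalid output."""
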