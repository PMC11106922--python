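"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage/argument problems exit 2, data
format problems exit 3, numerical failures exit 4.
"""


class HillodeError(Exception):
    """Base class for package errors."""


class ArgumentError(HillodeError, ValueError):
    """Invalid argument or configuration value."""


class DimensionError(HillodeError, ValueError):
    """Inconsistent array shapes."""


class DataFormatError(HillodeError, ValueError):
    """Malformed input file."""


class NumericalError(HillodeError, RuntimeError):
    """ODE solver or optimization failure; carries context in the message."""


class TrainingError(NumericalError):
    """Non-finite loss or other optimization breakdown."""
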