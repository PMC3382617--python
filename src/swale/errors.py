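"""Exception hierarchy.

CLI exit codes map ``InvalidInputError`` (and its subclass ``FormatError``)
to 2 and ``NumericalError`` to 3.
"""


class SwaleError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SwaleError, ValueError):
    """Invalid user input: bad shapes, ranges, configuration values."""


class FormatError(InvalidInputError):
    """Malformed input file (ragged rows, non-numeric or non-finite cells)."""


class NumericalError(SwaleError, ArithmeticError):
    """Numerical failure during estimation (singular systems, non-finite RSS)."""
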