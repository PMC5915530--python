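"""Exception types shared across the package.

``InputError`` marks rejected user input (bad sequence characters, malformed
files, mismatched grids); ``NumericalError`` marks a computation that could
not be completed (degenerate geometry, non-convergent fit). The CLI maps
them to exit codes 2 and 3 respectively.
"""


class RetromimicError(Exception):
    """Base class for package errors."""


class InputError(RetromimicError, ValueError):
    """Invalid or inconsistent input data."""


class NumericalError(RetromimicError, ArithmeticError):
    """A numerical procedure failed or is undefined for this input."""
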