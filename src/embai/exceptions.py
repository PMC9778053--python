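"""Exception hierarchy shared across the package.

Exit-code contract for the CLI: usage errors are handled by click (exit 1),
:class:`DataError` maps to exit 2, :class:`NumericalError` to exit 3.
"""


class EmbaiError(Exception):
    """Base class for all package errors."""


class DataError(EmbaiError, ValueError):
    """Invalid input data: bad shapes, unparseable files, domain violations."""


class NumericalError(EmbaiError, ArithmeticError):
    """Numerical failure mid-computation (non-finite values, singular systems)."""
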