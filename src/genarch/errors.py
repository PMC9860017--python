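"""Exception hierarchy for the pipeline.

Parsers raise :class:`FormatError` with a location, cross-file consistency
problems raise :class:`IntegrityError`, statistical-model preconditions raise
:class:`ModelError`, and numerical failures raise :class:`NumericError`.
"""


class GenarchError(Exception):
    """Base class for all package errors."""


class FormatError(GenarchError):
    """Malformed input file (names the column / line at fault)."""


class IntegrityError(GenarchError):
    """Inputs are individually valid but mutually inconsistent."""


class ArgumentError(GenarchError, ValueError):
    """Invalid argument value."""


class ModelError(GenarchError):
    """A statistical-model precondition is violated (e.g. negative variance)."""


class SizeError(GenarchError):
    """Problem too large for exact enumeration; shrink the region or K."""


class NumericError(GenarchError):
    """Numerical failure (non-PSD matrix, rank deficiency, ...)."""


class ConvergenceError(NumericError):
    """Iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
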