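"""Exception hierarchy shared across the package.

Errors distinguish *format* problems (a table or file that cannot be
interpreted at all), *consistency* problems (interpretable input that
contradicts itself, e.g. two different parents for one clone), and
*validation* problems (a structurally complete history that violates a
model invariant, e.g. a parent cycle).
"""


class MullerError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MullerError):
    """Input cannot be parsed: missing column, malformed JSON/DOT, etc."""


class ConsistencyError(MullerError):
    """Parseable input contradicts itself (duplicate values, bad labels)."""


class ValidationError(MullerError):
    """A clone history violates a structural invariant."""


class ParameterError(MullerError):
    """An argument is outside its documented range."""


class DegenerateInputError(MullerError):
    """Input is structurally valid but has no usable content."""
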