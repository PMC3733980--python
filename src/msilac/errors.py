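"""Exception hierarchy."""


class MsilacError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MsilacError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(MsilacError, ValueError):
    """Input is structurally valid but carries no usable signal (e.g. an
    all-zero gel)."""


class AlignmentError(MsilacError, ValueError):
    """No observed peak fell within tolerance of any theoretical bin."""


class DegenerateFitError(MsilacError, ValueError):
    """The mixture regression returned an all-zero solution, so the fraction
    of new synthesis is undefined."""
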