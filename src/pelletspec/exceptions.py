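"""Exception hierarchy shared across the package.

Validation problems (bad input shapes, vocabulary violations, misaligned
grids) raise :class:`ValidationError`; numerical breakdowns (non-convergence,
rank deficiency where a result is required) raise :class:`NumericalError`.
The CLI maps these onto exit codes 2 and 3 respectively.
"""


class PelletspecError(Exception):
    """Base class for all package errors."""


class ValidationError(PelletspecError):
    """Input fails a structural or vocabulary check."""


class AlignmentError(ValidationError):
    """Wavelength grids or sample identifiers do not line up."""


class RangeError(ValidationError):
    """A requested spectral range is outside the data's support."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but information-free (e.g. zero variance)."""


class StratificationError(ValidationError):
    """A resampling stratum cannot support the requested split."""


class NumericalError(PelletspecError):
    """An estimation routine failed to produce a usable result."""
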