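"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`PneumotachError`, so callers (and the CLI) can distinguish
validation failures from genuine bugs.
"""


class PneumotachError(Exception):
    """Base class for all package errors."""


class CoefficientError(PneumotachError, ValueError):
    """Invalid Rohrer coefficients (negative, or both zero)."""


class InputError(PneumotachError, ValueError):
    """Malformed or out-of-contract input data."""


class DomainError(PneumotachError, ValueError):
    """Argument outside the physical domain of a formula."""


class SingularDesignError(InputError):
    """Fit requested on data that cannot identify the parameters."""


class IdentifiabilityError(PneumotachError, RuntimeError):
    """Calibration maneuver pair admits no physical (K1, K2) solution."""


class BaselineError(InputError):
    """No quiescent baseline available for zero-offset correction."""


class AlignmentError(InputError):
    """Paired signals disagree in structure (e.g. breath counts differ)."""


class ParseError(InputError):
    """A file violated the expected dialect; message cites the line."""
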