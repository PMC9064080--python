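"""Exception hierarchy for the posture-entropy pipeline.

Every stage raises a subclass of :class:`PostureEntropyError`, so callers can
trap pipeline failures without masking programming errors.
"""


class PostureEntropyError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PostureEntropyError):
    """A data file does not conform to the expected dialect (e.g. a missing channel)."""


class ParseError(PostureEntropyError):
    """A cell in a data file could not be parsed as a number."""


class ConfigError(PostureEntropyError):
    """Invalid or missing configuration (sampling rate, filter spec, model kind...)."""


class UnloadedPlateError(PostureEntropyError):
    """The vertical force dropped below the guard threshold, so COP is undefined."""

    def __init__(self, index: int, fz_value: float, fz_min: float):
        self.index = index
        self.fz_value = fz_value
        self.fz_min = fz_min
        super().__init__(
            f"|Fz| = {abs(fz_value):.3g} N <= fz_min = {fz_min:g} N at sample {index}; "
            "the plate appears unloaded and COP is undefined"
        )


class LengthError(PostureEntropyError):
    """A series is too short for the requested operation."""


class UndefinedEntropyError(PostureEntropyError):
    """No template matches at length m: the conditional probability is undefined."""


class MissingCellError(PostureEntropyError):
    """A (subject, task) cell has no usable observations."""


class DegenerateDataError(PostureEntropyError):
    """Zero residual variance or similar degeneracy makes a test undefined."""


class DesignError(PostureEntropyError):
    """A request is outside the cohort design (unknown subject, task or repeat)."""
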