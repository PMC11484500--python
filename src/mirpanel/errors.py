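"""Exception hierarchy.

Every user-facing error derives from :class:`MirpanelError` so the CLI can
distinguish bad input (exit code 1) from internal failures (exit code 2).
"""


class MirpanelError(Exception):
    """Base class for all errors raised by mirpanel on invalid input."""


class InvalidDesignError(MirpanelError):
    """A synthetic-cohort or annotation design violates its invariants."""


class DomainError(MirpanelError):
    """A physical quantity is outside its admissible domain (e.g. C <= 0)."""


class DimensionMismatchError(MirpanelError):
    """Vector/matrix dimensions do not agree."""


class LabelError(MirpanelError):
    """Response labels are not binary {0, 1} or a class is missing."""


class FoldDegeneracyError(MirpanelError):
    """A cross-validation training fold lost one of the two classes."""


class UnsupportedDesignError(MirpanelError):
    """Contrast enumeration requested for a cohort design it does not cover."""


class DegenerateCalibrationError(MirpanelError):
    """Calibration points do not span two distinct concentrations."""


class MissingCalibrationError(MirpanelError):
    """A voltage measurement refers to an analyte without a fitted curve."""


class MalformedFileError(MirpanelError):
    """A delimited input file does not conform to the expected dialect."""


class DuplicateFeatureError(MalformedFileError):
    """An expression table contains a repeated feature column."""


class NonNumericDataError(MalformedFileError):
    """An expression table contains cells that cannot be parsed as numbers."""
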