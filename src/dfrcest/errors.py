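"""Exception hierarchy.

All package errors derive from :class:`DfrcError` so callers can catch one
base class; validation-style errors also derive from ``ValueError``.
"""


class DfrcError(Exception):
    """Base class for all errors raised by this package."""


class WaveformError(DfrcError, ValueError):
    """Invalid or unreadable waveform data."""


class NoBreathError(WaveformError):
    """No inspiration onset (negative-to-positive flow crossing) found."""


class InconsistentStepError(WaveformError):
    """Per-step summaries violate plateau pressure > PEEP."""


class UnidentifiableBreathError(DfrcError):
    """Regressor matrix too ill-conditioned to identify the lung model."""


class FlaggedFitError(DfrcError):
    """A downstream consumer refused a non-physiological (flagged) fit."""


class CalibrationError(DfrcError):
    """Cohort does not meet the requirements of a calibration routine."""


class BetaRangeError(CalibrationError):
    """Queried PEEP lies outside the calibrated range under refuse policy."""


class InsufficientDataError(DfrcError):
    """Not enough PEEP steps with measured dFRC for the requested method."""


class InvalidStepError(DfrcError):
    """A PEEP step lacks the quantities the estimator needs."""


class InfeasibleProfileError(DfrcError):
    """A beta profile that would force non-positive dFRC values."""


class ConfigError(DfrcError, ValueError):
    """Malformed run configuration (unknown keys, missing blocks...)."""
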