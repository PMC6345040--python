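"""Exception hierarchy for plate-screen analysis failures.

Every error raised by this package derives from :class:`PlateScreenError`,
so callers can catch one base class at pipeline boundaries while tests can
assert on the specific failure mode.
"""


class PlateScreenError(Exception):
    """Base class for all errors raised by platescreen."""


class PlateParseError(PlateScreenError):
    """A plate-grid CSV is malformed (wrong dimensions, non-numeric cell, ...)."""


class PlateMapError(PlateScreenError):
    """A plate-map CSV violates layout semantics (duplicate well, unknown role, ...)."""


class CoverageError(PlateScreenError):
    """A plate contains wells that the plate map does not annotate."""


class ControlError(PlateScreenError):
    """Control wells are missing or unusable (no blanks, non-positive control mean)."""


class DegenerateScreenError(PlateScreenError):
    """The screen carries no spread: the log-ratio standard deviation is zero."""


class MismatchedCompoundsError(PlateScreenError):
    """Reference and test conditions do not cover the same compound set."""


class CurveInputError(PlateScreenError):
    """A dose-response series does not satisfy fit preconditions."""


class NoAbsoluteIC50Error(PlateScreenError):
    """The fitted curve never crosses 50% of control, so no absolute IC50 exists."""


class SimulationConfigError(PlateScreenError):
    """A simulation configuration is infeasible or inconsistent."""


class ConfigError(PlateScreenError):
    """A pipeline run configuration is invalid."""
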