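"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`ItiesKitError`
so callers can catch the package's failures in one clause while still
distinguishing the degenerate-data cases (no peak, no plateau) that drive the
qualitative detection logic.
"""


class ItiesKitError(Exception):
    """Base class for all itieskit errors."""


class InvalidInputError(ItiesKitError, ValueError):
    """An argument violates a precondition (non-finite, non-positive, ...)."""


class DegreesOfFreedomError(ItiesKitError, ValueError):
    """Fewer data points than free parameters in a fit."""


class SingularDesignError(ItiesKitError, ValueError):
    """Regression design matrix is singular (e.g. a single concentration)."""


class FitError(ItiesKitError, RuntimeError):
    """A fit failed to converge or produced a physically invalid result."""


class SegmentationError(ItiesKitError, ValueError):
    """Potential program cannot be split into forward/backward sweeps."""


class NoPeakError(ItiesKitError, ValueError):
    """No extremum exceeding three times the local noise level was found.

    This is the "0" pathway of the qualitative presence call: a blank trace
    raises it rather than returning a spurious peak.
    """


class NotAPlateauError(ItiesKitError, ValueError):
    """The requested steady-state window is not flat enough to be a plateau."""


class AlignmentError(ItiesKitError, ValueError):
    """Two voltammograms do not share an overlapping potential range."""


class FormatError(ItiesKitError, ValueError):
    """A data file is malformed; the message names the offending line."""


class ConfigError(ItiesKitError, ValueError):
    """An analysis or simulation configuration is invalid."""
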