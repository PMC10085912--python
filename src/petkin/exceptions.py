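"""Exception hierarchy for petkin.

All petkin-specific errors derive from :class:`PetkinError` so callers can
catch the whole family; most also derive from the matching builtin
(``ValueError`` / ``RuntimeError``) so generic handling keeps working.
"""


class PetkinError(Exception):
    """Base class for all petkin errors."""


class FormatError(PetkinError, ValueError):
    """A file or table does not follow the expected layout."""


class ScheduleError(FormatError):
    """Frame start/end times violate the schedule invariants."""


class DimensionError(PetkinError, ValueError):
    """Array shapes or grids are inconsistent."""


class InsufficientDataError(PetkinError, ValueError):
    """Too few frames / data points for the requested operation."""


class ConfigurationError(PetkinError, ValueError):
    """Invalid model settings or options."""


class FitError(PetkinError, RuntimeError):
    """A model fit failed to converge.

    Attributes
    ----------
    status : optimiser status code or message, when available.
    """

    def __init__(self, message, status=None):
        super().__init__(message)
        self.status = status


class CollinearityError(FitError):
    """The regression design matrix is (numerically) rank deficient."""


class DegenerateDesignError(FitError):
    """A linear solve has a degenerate design (e.g. reference curve == 0)."""
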