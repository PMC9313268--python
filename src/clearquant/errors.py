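"""Exception hierarchy for clearquant."""


class ClearQuantError(Exception):
    """Base class for all clearquant errors."""


class InvalidSpecError(ClearQuantError, ValueError):
    """A phantom or protocol specification violates its invariants."""


class InvalidInputError(ClearQuantError, ValueError):
    """An input value or data structure violates a precondition."""


class RegionBoundsError(InvalidInputError):
    """A region does not lie entirely within the image bounds."""


class DegenerateRegionError(ClearQuantError):
    """A region's floored sample-intensity mean is at or below the floor.

    Callers may resample a replacement region.
    """


class ProtocolFailureError(ClearQuantError):
    """All resampling attempts for a run were exhausted on one image."""


class UndefinedStatisticError(ClearQuantError, ValueError):
    """A test statistic is undefined (e.g. zero variance everywhere)."""


class DegenerateRangeError(InvalidInputError):
    """Contrast stretch requested over a zero-width intensity range."""
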