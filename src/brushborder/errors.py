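"""Exception types shared across the brushborder pipeline."""


class BrushBorderError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(BrushBorderError, ValueError):
    """A generator or operation parameter is outside its valid range."""


class InvalidInputError(BrushBorderError, ValueError):
    """An input object violates the operation's preconditions."""


class InsufficientPointsError(InvalidInputError):
    """A point-pattern operation needs more points than were supplied."""


class InsufficientDataError(InvalidInputError):
    """A group comparison needs more non-missing observations per group."""


class UndefinedRingError(BrushBorderError):
    """The power spectrum has no identifiable first-order ring
    (e.g. a constant image)."""


class PlacementError(BrushBorderError):
    """Non-overlapping object placement failed after bounded retries."""


class DegenerateLineError(InvalidInputError):
    """Line-scan endpoints are too close to define a scan direction."""


class CannotAlignError(InvalidInputError):
    """The reference channel has no positive maximum to align on."""


class InvalidAnnotationError(InvalidInputError):
    """A manual annotation (polyline pair) is geometrically inconsistent."""
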