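"""Exception hierarchy for enzybind.

All package-specific failures derive from :class:`EnzybindError` so callers
can catch one base class at pipeline boundaries.
"""


class EnzybindError(Exception):
    """Base class for all enzybind errors."""


class InvalidDesignError(EnzybindError):
    """An assay design violates its invariants (non-positive or non-increasing
    concentration grids, missing reference points, ...)."""


class DegenerateControlError(EnzybindError):
    """The uninhibited control produced no enzymatic signal (a - A <= 0), so
    the inhibition rate is undefined."""


class InsufficientDataError(EnzybindError):
    """Too few usable points remain for the requested fit."""


class NoPeakError(EnzybindError):
    """A spectrum is flat: no emission maximum can be located."""
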