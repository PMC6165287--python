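"""Exceptions and warnings raised across the silhouette-processing pipeline."""


class GaitSilError(ValueError):
    """Base class for all gaitsil errors."""


class SequenceError(GaitSilError):
    """Invalid or unreadable silhouette sequence."""


class InsufficientCyclesError(GaitSilError):
    """Fewer gait events than the requested computation needs."""


class InsufficientStepsError(GaitSilError):
    """Not enough labelled steps on one or both sides."""


class NoNetTranslationError(GaitSilError):
    """The walker shows no net horizontal displacement."""


class DegenerateInputError(GaitSilError):
    """Input is formally valid but carries no usable signal (uniform image,
    single-pixel region, zero duration, ...)."""


class NoFootFlatWarning(UserWarning):
    """A half cycle yielded no usable foot-flat footprint and was skipped."""


class SideAssignmentWarning(UserWarning):
    """Foot-side votes were not unanimous; parity fixed by majority."""
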