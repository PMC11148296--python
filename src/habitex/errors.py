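"""Exception hierarchy for the habitex pipeline.

Every stage raises a subclass of :class:`HabitexError` so the orchestrator
can tag failures with the stage that produced them.
"""


class HabitexError(Exception):
    """Base class for all habitex errors."""


class GridMismatchError(HabitexError):
    """Volumes in a series do not share shape/spacing/orientation."""


class DegenerateVOIError(HabitexError):
    """The VOI mask is empty (on load or after resampling)."""


class DegenerateIntensityError(HabitexError):
    """Volume has zero intensity variance; normalization undefined."""


class EmptyMalignantSubregionError(HabitexError):
    """No washout or plateau voxels; the study is excluded from extraction."""


class InvalidArchetypeError(HabitexError):
    """Unknown or inconsistent kinetic-curve archetype."""


class GeometryError(HabitexError):
    """Phantom lesion does not fit inside the simulation grid."""


class InvalidScaleError(HabitexError):
    """Filter scale is too large for the field of view."""


class InvalidCohortError(HabitexError):
    """Cohort labels contain fewer than two classes."""


class UndefinedTestError(HabitexError):
    """Contingency table has a zero marginal; chi-square undefined."""


class SelectionError(HabitexError):
    """Feature selection asked for more features than are available."""


class StageError(HabitexError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {type(original).__name__}: {original}")
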