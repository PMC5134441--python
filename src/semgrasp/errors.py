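"""Exception hierarchy shared across the pipeline."""


class SemgraspError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(SemgraspError, ValueError):
    """A configuration value is outside its validated range."""


class DegenerateInputError(SemgraspError, ValueError):
    """The input is too short / empty for the requested operation."""


class InvalidInputError(SemgraspError, ValueError):
    """Input violates a structural precondition (shape, n-gram kind, ...)."""


class AlignmentError(SemgraspError, ValueError):
    """Per-channel epoch grids or label/feature grids disagree."""


class InvalidEventsError(SemgraspError, ValueError):
    """A kinematic event table violates ordering/overlap invariants."""


class UndefinedMetricError(SemgraspError, ZeroDivisionError):
    """A requested metric has no defined value (e.g. 0/0 percentage)."""


class ClassificationError(SemgraspError, RuntimeError):
    """No class produced a finite score for an observation."""


class ValidationError(SemgraspError, ValueError):
    """A file or config failed validation; message names file/field."""
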