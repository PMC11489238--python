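"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`ToxconcordError` so callers can
distinguish bad inputs from genuine bugs; the pipeline driver re-raises them
tagged with the stage name.
"""


class ToxconcordError(Exception):
    """Base class for all package errors."""


class SchemaError(ToxconcordError):
    """A delimited file is missing a required column."""


class InputError(ToxconcordError):
    """An input file is empty or unreadable."""


class VocabularyError(ToxconcordError):
    """An effect category is not in the controlled vocabulary."""


class NormalizationError(ToxconcordError):
    """A housekeeping/reference gene is absent or undetected in a sample."""


class DegenerateControlError(ToxconcordError):
    """A solvent-control net signal is zero or negative."""


class SelectionError(ToxconcordError):
    """No tested concentration satisfies the viability rule."""


class MissingDataError(ToxconcordError):
    """Not enough replicates to compute the requested quantity."""


class DomainError(ToxconcordError):
    """A value is outside the mathematical domain of an operation."""


class StageError(ToxconcordError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage {stage!r} failed: {original}")
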