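"""Exception hierarchy shared across the package."""


class MotuforgeError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(MotuforgeError):
    """Sequences do not form a valid alignment (e.g. unequal lengths)."""


class FormatError(MotuforgeError):
    """A file violates its format contract (e.g. duplicate ids)."""


class ValidationError(MotuforgeError):
    """Inputs are well-formed but semantically inconsistent."""


class SingleSpeciesError(MotuforgeError):
    """An operation requiring >= 2 species received only one."""


class UndefinedComparisonError(MotuforgeError):
    """A pairwise comparison has no jointly resolved sites."""


class PipelineError(MotuforgeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
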