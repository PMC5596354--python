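"""Exception hierarchy for the CCRIT pipeline."""


class CCRITError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CCRITError):
    """Input data violates a format contract (shapes, pages, columns)."""


class DegenerateInputError(CCRITError):
    """An image is degenerate for the requested operation (e.g. constant)."""


class NoPlateauError(CCRITError):
    """The spot-intensity curve has no usable plateau region."""


class EmptyMaskError(CCRITError):
    """A binary mask required to contain pixels is empty."""


class GeometryError(CCRITError):
    """A geometric construction is impossible or ill-posed."""


class AssignmentError(CCRITError):
    """Cell-to-ommatidium assignment cannot proceed."""


class StageError(CCRITError):
    """Wraps an error with the pipeline stage in which it occurred."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
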