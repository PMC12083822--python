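"""Exception hierarchy shared across the pipeline."""


class EpiDrugScreenError(Exception):
    """Base class for all package errors."""


class ParameterError(EpiDrugScreenError, ValueError):
    """An argument is outside its documented domain."""


class MissingDataError(EpiDrugScreenError, KeyError):
    """A required observation (timepoint, control sample, ...) is absent."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class UnknownEntityError(EpiDrugScreenError, KeyError):
    """A compound, cell line or gene id is not known to the object queried."""

    def __str__(self) -> str:
        return self.args[0] if self.args else ""


class FormatError(EpiDrugScreenError, ValueError):
    """A file does not conform to its documented schema."""


class DegenerateInputError(EpiDrugScreenError, ValueError):
    """Input is structurally valid but the operation is undefined on it."""


class StageError(EpiDrugScreenError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
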