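"""Exception hierarchy for the meripairray pipeline."""


class MeripArrayError(Exception):
    """Base class for all package errors."""


class ValidationError(MeripArrayError):
    """Raised when an input table or configuration violates its contract."""


class StageError(MeripArrayError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
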