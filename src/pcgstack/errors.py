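"""Exception types shared across the pipeline."""


class PCGStackError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PCGStackError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(PCGStackError, ValueError):
    """An input array/table violates an operation's precondition."""


class DegenerateInputError(InvalidInputError):
    """Input is constant or otherwise carries no usable information."""


class NotFittedError(PCGStackError, RuntimeError):
    """A model was used before fitting."""


class UnavailableBackboneError(PCGStackError, RuntimeError):
    """A pretrained CNN backbone was requested but its weights/runtime are absent."""


class StageError(PCGStackError, RuntimeError):
    """Wraps an error raised inside a pipeline stage with stage/sample context."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        self.detail = detail
        super().__init__(f"[{stage}] {detail}")
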