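"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented contract.

    Messages name the offending field, sample or group so callers (and the
    CLI, which maps this class to exit code 1) can report actionable errors.
    """


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
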