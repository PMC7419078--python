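"""Exception hierarchy shared across the pipeline."""


class UgtShapeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(UgtShapeError, ValueError):
    """A file or selection string could not be parsed."""


class EmptyInputError(UgtShapeError, ValueError):
    """An input that must be non-empty was empty."""


class ConfigError(UgtShapeError, ValueError):
    """A run configuration failed validation; message aggregates all problems."""


class TrainingDivergedError(UgtShapeError, RuntimeError):
    """Optimisation produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged at epoch {epoch}: non-finite loss")
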