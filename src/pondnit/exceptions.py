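"""Package exception hierarchy."""


class PondnitError(Exception):
    """Base class for pondnit errors."""


class ConfigurationError(PondnitError, ValueError):
    """Invalid scenario / run configuration."""


class SchemaError(PondnitError, ValueError):
    """A CSV/YAML input does not match its declared schema."""


class IntegrationError(PondnitError, RuntimeError):
    """ODE solver failure; carries the time at which integration stopped."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class UndefinedMetricError(PondnitError, ValueError):
    """Goodness-of-fit metric undefined (e.g. zero observed variance)."""


class InitializationError(PondnitError, ValueError):
    """A sampler was started from an infeasible point."""


class StageError(PondnitError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
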