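"""Exception hierarchy shared across the package."""


class SpikemodeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SpikemodeError, ValueError):
    """An input violates a documented precondition."""


class UnachievableError(SpikemodeError):
    """A requested transformation cannot be realized for the given data."""


class ConservationError(SpikemodeError):
    """Internal consistency failure: the attribution decomposition does not
    reproduce the recorded membrane potential."""


class FitError(SpikemodeError):
    """A nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class TrainingError(SpikemodeError):
    """Training diverged or produced non-finite values; carries context."""

    def __init__(self, message, epoch=None, batch=None):
        super().__init__(message)
        self.epoch = epoch
        self.batch = batch


class StageError(SpikemodeError):
    """A pipeline stage failed; tagged with the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class DependencyError(SpikemodeError):
    """A pipeline stage requires output of a stage that has not run."""

    def __init__(self, missing_stage, message=None):
        super().__init__(message or f"missing required stage output: {missing_stage}")
        self.missing_stage = missing_stage


class CorruptionError(SpikemodeError):
    """A stored artifact does not match its recorded checksum."""
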