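"""Exception hierarchy for the wing-kinematics pipeline."""


class WingkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(WingkinError, ValueError):
    """A synthetic bone specification violates its invariants."""


class ConfigurationError(WingkinError, ValueError):
    """A pipeline or posing configuration is incomplete or inconsistent."""


class InvalidTransformError(WingkinError, ValueError):
    """A rotation matrix is not a proper orthonormal rotation."""


class EmptyInputError(WingkinError, ValueError):
    """An operation received an empty point cloud."""


class IllPosedFitError(WingkinError, ValueError):
    """A moving cloud is rank-deficient; its pose cannot be identified."""


class OptimizationFailureError(WingkinError, RuntimeError):
    """No optimization start converged. Carries the best iterate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class DegenerateFrameError(WingkinError, ValueError):
    """Wing-frame landmarks are collinear; no plane is defined."""


class ReportError(WingkinError, ValueError):
    """A kinematics report cannot be assembled from the supplied fits."""


class UnreachableConfigurationError(WingkinError, RuntimeError):
    """The mechanism loop cannot close at the requested drive angle."""


class BranchJumpError(WingkinError, RuntimeError):
    """The mechanism solution jumped between assembly branches."""


class InvalidRoutingError(WingkinError, ValueError):
    """A tendon routing does not span two distinct links."""


class ValidationError(WingkinError, ValueError):
    """A pipeline config failed validation; lists every problem found."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid config: " + "; ".join(self.problems))


class PipelineStageError(WingkinError, RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
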