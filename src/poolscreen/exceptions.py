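"""Exception types shared across the package."""


class PoolscreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PoolscreenError, ValueError):
    """A simulation or analysis parameter is outside its valid domain."""


class SimulationCollapseError(PoolscreenError, RuntimeError):
    """The simulated cell pool went extinct at some stage.

    Carries the stage label so the failing step can be identified.
    """

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"cell pool is empty at stage '{stage}'")


class DegenerateSampleError(PoolscreenError, ValueError):
    """A sample column is unusable (e.g. zero total counts)."""


class UndefinedWidthError(PoolscreenError, ValueError):
    """Library width is undefined because the 10th percentile is zero."""


class CountTableParseError(PoolscreenError, ValueError):
    """A count table file violates the expected format."""
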