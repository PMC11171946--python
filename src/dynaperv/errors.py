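"""Exception and warning types shared across the package."""


class DynapervError(Exception):
    """Base class for all package-specific errors."""


class InvalidDensityError(DynapervError, ValueError):
    """A density or delta input is non-finite or otherwise unusable."""


class ConfigurationError(DynapervError, ValueError):
    """A simulation or pipeline configuration is inconsistent or infeasible."""


class PlacementError(DynapervError, ValueError):
    """ROIs cannot be placed on the clot (e.g. clot too short for n non-overlapping ROIs)."""


class SamplingError(DynapervError, ValueError):
    """An ROI contains no voxels, or sampling a measurement failed."""


class SeparationError(DynapervError, ValueError):
    """Complete separation in a logistic fit; the message names the offending category."""


class ZeroCellError(DynapervError, ValueError):
    """A 2x2 table has a zero cell, so the odds ratio is zero or infinite.

    Raised instead of returning a non-finite number; pass ``correction="haldane"``
    to obtain a corrected finite estimate.
    """


class FlowConsistencyError(DynapervError, ValueError):
    """An exclusion step would drive the running patient count negative."""


class PipelineError(DynapervError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


class PlausibilityWarning(UserWarning):
    """Input is usable but outside the plausible clinical range."""
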