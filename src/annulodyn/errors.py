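"""Exception hierarchy shared by all annulodyn stages."""


class AnnulodynError(Exception):
    """Base class for all errors raised by annulodyn."""


class ValidationError(AnnulodynError):
    """A parameter, protocol field or input array violates its contract."""


class FormatError(AnnulodynError):
    """A distance-table / analogue / calibration file does not match its dialect."""


class AlignmentError(AnnulodynError):
    """The sonomicrometry and analogue streams cannot be synchronized."""


class DetectionError(AnnulodynError):
    """Beat or landmark detection failed (too few R peaks, no dP/dt extrema)."""


class CoverageError(AnnulodynError):
    """A series does not cover the requested beat windows or landmarks."""


class CalibrationError(AnnulodynError):
    """Force calibration is under-determined or physically implausible."""


class ReconstructionError(AnnulodynError):
    """A distance matrix cannot be embedded (too many missing entries)."""


class ModelError(AnnulodynError):
    """The repeated-measures design is singular or otherwise unfittable."""


class PipelineError(AnnulodynError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
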