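"""Exception hierarchy for the vicurve package."""


class VicurveError(Exception):
    """Base class for all package-specific errors."""


class InsufficientDataError(VicurveError):
    """Too few measurement points for the requested operation."""


class MissingDistanceError(VicurveError):
    """A required test distance is absent from a patient's profile."""


class DomainError(VicurveError):
    """A point lies outside a fitted curve's domain (extrapolation refused)."""


class CalibrationError(VicurveError):
    """The QoL slope calibration cannot attain the requested correlation."""


class ConstantInputError(VicurveError):
    """A statistical test is undefined on constant input."""


class UndefinedCorrelationError(VicurveError):
    """Correlation undefined (zero variance in one of the variables)."""


class EmptyCohortError(VicurveError):
    """Complete-case filtering removed every patient."""


class PipelineError(VicurveError):
    """A pipeline stage failed; message carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
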