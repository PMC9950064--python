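"""Exception types shared across the toolkit."""


class PainlearnError(Exception):
    """Base class for all package-specific errors."""


class UnreachableProbabilityError(PainlearnError, ValueError):
    """Requested detection probability lies outside the psychometric range."""


class NoDetectionError(PainlearnError, RuntimeError):
    """The observer never detected a stimulus below the intensity cap."""


class InvalidMeasurementError(PainlearnError, ValueError):
    """A psychophysical measurement violates its preconditions."""


class ModelDivergenceError(PainlearnError, RuntimeError):
    """A filter update produced a non-positive precision.

    Carries the (0-based) trial index at which the update failed, if known.
    """

    def __init__(self, message: str, trial: int | None = None):
        super().__init__(message)
        self.trial = trial


class IncompleteSessionError(PainlearnError, ValueError):
    """A behavioural session is missing trials or responses."""


class IncompleteRampError(PainlearnError, ValueError):
    """A cuff-pressure ramp ended without a stop event or reaching the cap."""


class FitFailureError(PainlearnError, RuntimeError):
    """Every optimisation start diverged or failed."""


class SchemaError(PainlearnError, ValueError):
    """A session or trace file violates the expected CSV schema."""
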