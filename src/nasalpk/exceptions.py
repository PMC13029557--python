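"""Exception hierarchy for nasalpk."""


class NasalPKError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NasalPKError, ValueError):
    """A rate constant, volume, dose or fraction violates its admissibility bounds."""


class DegeneratePoleError(NasalPKError, ValueError):
    """Two exponential rates coincide (within tolerance), so the simple-pole
    partial-fraction inversion is not applicable.

    Confluent (t*exp) solutions are deliberately not provided; callers should
    perturb the offending rate or treat the fit as inadmissible.
    """


class InconsistentRatesError(NasalPKError, ValueError):
    """A derived rate constant fell outside its physically admissible range,
    signalling mutually inconsistent fitted inputs.  The raw value is carried
    in ``value`` for diagnosis; it is never silently clipped."""

    def __init__(self, message: str, value: float | None = None):
        super().__init__(message)
        self.value = value


class PipelineError(NasalPKError, RuntimeError):
    """The end-to-end analysis cannot proceed (e.g. missing IV plasma data)."""
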