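"""Exception hierarchy.

Errors are split into three families so that callers (and the CLI, which
maps them onto distinct exit codes) can tell apart a bad configuration,
bad input data, and a failure arising during computation.
"""


class RumorDynError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RumorDynError):
    """A configuration object or file violates its invariants."""


class InputError(RumorDynError):
    """Input data violate a precondition (bad shape, range, or emptiness)."""


class ComputeError(RumorDynError):
    """A computation could not be completed on otherwise valid input."""


class IntegrationError(ComputeError):
    """ODE integration produced a non-finite state."""

    def __init__(self, t_bad: float, message: str | None = None):
        self.t_bad = t_bad
        super().__init__(message or f"non-finite state first produced at t={t_bad!r}")


class DegenerateSeriesError(ComputeError):
    """An intensity series has zero maximum, so relative thresholds are undefined."""


class PhaseDegenerateError(ComputeError):
    """A lifecycle phase has zero duration, so its transition rate is undefined."""

    def __init__(self, phase: str):
        self.phase = phase
        super().__init__(f"zero-duration phase {phase!r}: transition rate undefined")


class MissingStageError(InputError):
    """One or more propagation stages are absent from a corpus."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"stages absent from corpus: {', '.join(self.missing)}")


class UndefinedConditionalError(ComputeError):
    """A conditional probability is requested for a condition never observed."""


class DegenerateFitError(ComputeError):
    """A regression fit is degenerate (zero variance in the predictor)."""
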