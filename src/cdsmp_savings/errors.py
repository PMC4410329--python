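"""Exception hierarchy for the estimator.

Every domain failure derives from :class:`EstimatorError` so callers (and the
CLI) can distinguish validation problems from programming errors.
"""


class EstimatorError(Exception):
    """Base class for all estimator-domain errors."""


class UndefinedDenominatorError(EstimatorError):
    """A wave has a zero denominator, so its proportion is undefined."""

    def __init__(self, wave: str):
        self.wave = wave
        super().__init__(f"undefined denominator: no respondents at wave '{wave}'")


class InvalidProgramCostError(EstimatorError):
    """Program-cost model cannot produce a positive per-participant cost."""


class IngestionError(EstimatorError):
    """Participant CSV could not be ingested (carries a line number when known)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnderageParticipantError(IngestionError):
    """Participant is younger than 18; the program targets adults."""


class ConfigError(EstimatorError):
    """Configuration JSON violates the schema (carries a JSON-pointer path)."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


class InvalidScenarioError(EstimatorError):
    """Reach scenario is malformed (e.g. zero expected participants)."""


class InfeasibleSpecError(EstimatorError):
    """EXACT-mode cohort spec cannot be realized with integer counts."""


class ReportFormatError(EstimatorError):
    """Unknown report output format."""
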