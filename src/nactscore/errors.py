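"""Exception hierarchy for nactscore."""


class NactScoreError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NactScoreError):
    """Input data or configuration violates a documented invariant."""


class DegenerateOutcomeError(NactScoreError):
    """The binary outcome has only one class; the model is not identifiable."""


class SeparationError(NactScoreError):
    """Perfect (or quasi-perfect) separation: the MLE does not exist."""


class RankDeficientError(NactScoreError):
    """The design matrix is (numerically) rank deficient."""


class ConvergenceError(NactScoreError):
    """IRLS failed to converge within the iteration budget."""


class PipelineError(NactScoreError):
    """A pipeline stage failed; carries stage name and cohort for diagnosis."""

    def __init__(self, stage: str, cohort: str | None, cause: BaseException | str):
        self.stage = stage
        self.cohort = cohort
        self.cause = cause
        where = f"stage '{stage}'" + (f", cohort '{cohort}'" if cohort else "")
        super().__init__(f"pipeline failed at {where}: {cause}")
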