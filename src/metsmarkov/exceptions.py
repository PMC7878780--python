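"""Exception hierarchy for metsmarkov."""


class MetsMarkovError(Exception):
    """Base class for all package errors."""


class TopologyError(MetsMarkovError):
    """A transition outside the allowed six-state topology was requested."""


class ParameterError(MetsMarkovError):
    """Parameter values outside the model's domain (non-finite, non-positive)."""


class DataError(MetsMarkovError):
    """Panel data violating the observation-scheme invariants."""


class MissingBiomarkerError(DataError):
    """A biomarker needed for a criterion is missing and no treatment flag covers it."""

    def __init__(self, criterion: str, subject_id=None):
        self.criterion = criterion
        self.subject_id = subject_id
        who = f" (subject {subject_id})" if subject_id is not None else ""
        super().__init__(
            f"cannot evaluate criterion '{criterion}'{who}: biomarker missing "
            f"and no covering treatment flag"
        )


class SpecError(MetsMarkovError):
    """Invalid cohort-simulation specification."""


class EstimationError(MetsMarkovError):
    """Estimation failed in a way that requires user action (e.g. refit needed)."""
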