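"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """An input value violates a clinical-range or type invariant."""


class SchemaError(ValidationError):
    """A cohort file does not conform to the documented CSV schema."""


class EvaluationError(RuntimeError):
    """A diagnostic evaluation cannot be carried out on the given cohort."""


class SingleClassError(EvaluationError):
    """The cohort contains only operative or only nonoperative records."""


class PerfectSeparationError(EvaluationError):
    """A logistic design matrix completely separates the outcome classes."""


class ConsistencyError(ValueError):
    """Reported confusion-matrix cells contradict the supplied group totals."""
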