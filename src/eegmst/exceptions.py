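"""Exception hierarchy shared across the pipeline."""


class EegMstError(Exception):
    """Base class for all package errors."""


class FormatError(EegMstError, ValueError):
    """A file does not parse under the named standard."""


class ContentError(EegMstError, ValueError):
    """A file parses but its content violates a precondition."""


class ParameterError(EegMstError, ValueError):
    """An argument is outside its admissible range."""


class QualityError(EegMstError, RuntimeError):
    """Data fail a quality gate (e.g. too few artifact-free epochs)."""


class DesignError(EegMstError, ValueError):
    """A statistical design is malformed (missing group, unknown label)."""


class SplitError(EegMstError, ValueError):
    """A train/test split cannot satisfy its stratification contract."""


class MetricUndefinedError(EegMstError, ValueError):
    """A graph metric is undefined for the given tree size."""


class EvaluationError(EegMstError, RuntimeError):
    """A model evaluation step is degenerate (e.g. single-class test set)."""
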