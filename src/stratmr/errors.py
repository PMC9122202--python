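"""Exception hierarchy.

Every failure mode the pipeline can hit has a dedicated class so callers
(and the CLI) can report the stage and cohort context without string
matching.
"""


class StratMRError(Exception):
    """Base class for all package errors."""


class ValidationError(StratMRError):
    """An input value violates a documented invariant."""


class SchemaError(ValidationError):
    """A table is missing required columns or has malformed ones."""


class ParseError(StratMRError):
    """A file could not be parsed; message names the offending line."""


class AlignmentError(ValidationError):
    """Sample identifiers or vector lengths do not line up."""


class AlleleMismatchError(ValidationError):
    """A dosage record's counted allele matches neither weight allele."""


class EmptyInstrumentError(StratMRError):
    """No variant overlap between the dosage panel and the weight table."""


class SingularDesignError(StratMRError):
    """A regression design matrix is rank-deficient."""


class ConvergenceError(StratMRError):
    """A likelihood maximisation failed to converge (e.g. monotone
    likelihood from complete separation in a Cox model)."""


class SeparationError(ConvergenceError):
    """Perfect separation in a logistic model."""


class NoEventsError(StratMRError):
    """A survival model was requested on data without any events."""


class NoVariationError(StratMRError):
    """A binary outcome has a single class."""


class EmptyMetaError(StratMRError):
    """Meta-analysis called with zero estimates."""


class ContractError(StratMRError):
    """Estimates passed to a pooling step disagree on model or stratum."""


class WeakInstrumentError(StratMRError):
    """First-stage coefficient is exactly zero; the ratio is undefined."""


class ConfigurationError(StratMRError):
    """A simulation or pipeline configuration is infeasible."""
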