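"""Exception hierarchy for the pipeline.

Exit-code mapping used by the CLI: ValidationError-family -> 1,
anything else raised during a stage -> 2.
"""


class BasalmirError(Exception):
    """Base class for all package errors."""


class ParseError(BasalmirError):
    """A file could not be parsed (malformed TSV, empty file, ...)."""


class SchemaError(BasalmirError):
    """A table is missing required columns or uses unknown vocabulary."""


class ValidationError(BasalmirError):
    """A value violates a domain invariant (duplicate ids, out-of-range score, ...)."""


class ConfigError(ValidationError):
    """A configuration value is invalid or an unknown key was supplied."""


class ConfoundingError(BasalmirError):
    """The group factor is aliased with the chip covariate; the model is not estimable."""


class AssumptionError(BasalmirError):
    """Prevalence assumptions produce an impossible derived quantity."""


class StageError(ValidationError):
    """An operation was applied to a matrix at the wrong processing stage."""
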