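"""Exceptions shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the field."""


class UndefinedRateError(ZeroDivisionError):
    """A rate was requested over an empty denominator."""


class NotComputableError(ValueError):
    """A per-patient measure's preconditions are not met (patient excluded)."""


class SchemaError(KeyError):
    """An input table is missing a required column."""
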