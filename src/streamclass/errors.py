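"""Exception hierarchy shared across the classification layers."""


class StreamClassError(Exception):
    """Base class for all package errors."""


class SchemaError(StreamClassError):
    """A required column or field is absent or of the wrong kind."""


class IntegrityError(StreamClassError):
    """Referential integrity violated (duplicate COMID, dangling edge)."""


class ConfigError(StreamClassError):
    """Invalid configuration value (unknown unit tag, bad rate, missing seed)."""


class TopologyError(StreamClassError):
    """Graph-structural violation (cycle where a DAG is required)."""


class DerivationError(StreamClassError):
    """A data-driven derivation cannot proceed (too few orders, non-monotone medians)."""


class DegenerateInputError(StreamClassError):
    """Input carries no usable signal (constant matrix, single class)."""


class InsufficientDataError(StreamClassError):
    """Too few observations to fit the requested model."""


class ImputationError(StreamClassError):
    """Missing-value imputation cannot proceed (all-missing or >=50% column)."""
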