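"""Exception hierarchy shared by all caparch modules."""


class CapArchError(Exception):
    """Base class for all caparch errors."""


class ParameterError(CapArchError, ValueError):
    """An argument is outside its documented domain."""


class UndefinedStatisticError(CapArchError, ValueError):
    """The requested statistic is undefined for the given input
    (e.g. an all-zero margin in a 2x2 table, or a monomorphic site)."""


class DataError(CapArchError, ValueError):
    """Input data are malformed or internally inconsistent."""


class SchemaError(DataError):
    """A tabular input is missing a required column."""


class ConfigError(DataError):
    """A scenario configuration file cannot be parsed or validated."""
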