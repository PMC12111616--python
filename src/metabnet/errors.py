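"""Exception hierarchy shared across the pipeline stages."""


class MetabnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MetabnetError):
    """Invalid design, parameter, or pipeline configuration."""


class ParseError(MetabnetError):
    """Malformed input table; message carries row/column coordinates."""


class UndefinedStatisticError(MetabnetError):
    """A statistic is requested on data where it is not defined
    (e.g. %CV from fewer than two QC injections)."""


class UnsupportedOracleError(MetabnetError):
    """The closed-form oracle does not cover the requested generator
    configuration (e.g. unequal covariance across groups)."""
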