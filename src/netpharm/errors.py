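"""Exception hierarchy shared across pipeline stages."""


class NetpharmError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(NetpharmError):
    """An input table is missing a required column or field."""


class ParseError(NetpharmError):
    """A line of an input file could not be parsed."""


class ParameterError(NetpharmError):
    """Arguments are out of range or mutually infeasible."""


class ConvergenceError(NetpharmError):
    """An iterative solver failed to converge within its budget."""


class CliqueCapError(NetpharmError):
    """Maximal-clique enumeration exceeded the configured cap."""


class EmptyCoreError(NetpharmError):
    """A median-filter round removed every node."""


class ConfigError(NetpharmError):
    """A run configuration failed validation."""
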