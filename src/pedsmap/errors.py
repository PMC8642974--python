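"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (config error = 2, data
error = 3, anything else = 1).
"""


class PedsmapError(Exception):
    """Base class for package errors."""


class ConfigError(PedsmapError):
    """Invalid configuration (bad parameter values, malformed config file)."""


class DataError(PedsmapError):
    """Invalid or inconsistent input data (bad counts, unsorted tables, ...)."""


class SelectionError(DataError):
    """Phenotypic selection matched no plants; the breeding scheme cannot advance."""
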