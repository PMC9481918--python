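"""Exception hierarchy shared by the library and the command line."""


class IsletScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(IsletScreenError):
    """Invalid configuration or parameter values (CLI exit code 2)."""


class DataValidationError(IsletScreenError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class StatisticalError(IsletScreenError):
    """A statistical procedure cannot proceed, e.g. a degenerate null (CLI exit code 4)."""
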