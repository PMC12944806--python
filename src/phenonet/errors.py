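"""Exception hierarchy with exit-code mapping for the command line interface."""


class PhenonetError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(PhenonetError):
    """Invalid configuration or unusable option combination."""

    exit_code = 2


class DataError(PhenonetError):
    """Malformed or inconsistent input data."""

    exit_code = 3
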