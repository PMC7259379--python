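"""Exception hierarchy shared across the package."""


class OmicregError(Exception):
    """Base class for all package errors."""


class ConfigError(OmicregError):
    """Invalid run or simulation configuration (CLI exit code 2)."""


class DataError(OmicregError):
    """Malformed or inconsistent input data (CLI exit code 3)."""
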