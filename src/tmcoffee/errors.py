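"""Exception hierarchy shared across the package."""


class TMCoffeeError(Exception):
    """Base class for all tmcoffee errors."""


class DataError(TMCoffeeError):
    """Malformed or inconsistent input data."""


class ConfigError(TMCoffeeError):
    """Invalid parameter or configuration value."""
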