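"""Exception types shared across the package."""


class VrgazeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(VrgazeError):
    """An input table does not carry the columns the reader was told to expect."""


class DataError(VrgazeError):
    """An input file is structurally readable but violates a data contract."""


class ConfigError(VrgazeError):
    """A configuration value is outside its admissible range."""
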