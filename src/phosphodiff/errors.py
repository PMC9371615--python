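"""Exception hierarchy shared across the pipeline stages."""


class PhosphodiffError(Exception):
    """Base class for all pipeline errors."""


class InputError(PhosphodiffError, ValueError):
    """Malformed or inconsistent input data (tables, matrices, bounds)."""


class ConfigError(PhosphodiffError, ValueError):
    """Invalid configuration: bad parameters, missing columns, missing seed."""
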