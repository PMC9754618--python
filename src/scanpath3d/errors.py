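"""Exception types raised at the package's validation boundaries."""


class SchemaError(ValueError):
    """A required column or field is missing from an input file."""


class ValidationError(ValueError):
    """An input value violates a data-model invariant."""


class ConfigError(ValueError):
    """A configuration value is out of its admissible range."""
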