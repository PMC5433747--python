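"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A run configuration is invalid (bad value, unknown key, bad type)."""


class InvalidTraitError(ValueError):
    """A species trait violates its domain (e.g. non-positive seed mass)."""


class UndefinedChangeError(ValueError):
    """Percent change requested relative to a zero baseline."""
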