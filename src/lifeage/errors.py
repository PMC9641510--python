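"""Exception hierarchy shared across the package."""


class LifeAgeError(Exception):
    """Base class for all package-specific errors."""


class InputError(LifeAgeError, ValueError):
    """Malformed or out-of-range user input (wrong item count, rating out of range...)."""


class ConfigError(LifeAgeError, ValueError):
    """Invalid or incomplete configuration (missing category, non-positive SD...)."""


class MissingDataError(LifeAgeError, ValueError):
    """A required field or domain is absent; no imputation is performed."""
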