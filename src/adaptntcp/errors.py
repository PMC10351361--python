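"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the offending field."""


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""
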