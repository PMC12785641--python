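"""Exception hierarchy."""


class XtalgenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(XtalgenError, ValueError):
    """Invalid configuration value (bad distribution spec, unknown element...)."""


class DomainError(XtalgenError, ValueError):
    """Input outside the mathematical domain of an operation."""
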