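"""Exception types shared across the package."""


class OrganRepError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OrganRepError):
    """A configuration value or required input column is invalid or missing."""


class ValidationError(OrganRepError, ValueError):
    """Input data violates a documented precondition."""


class NewickParseError(OrganRepError):
    """A Newick tree statement could not be parsed."""
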