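"""Exception types shared across the package."""


class IrimapError(Exception):
    """Base class for all package errors."""


class FormatError(IrimapError, ValueError):
    """A file or table violates the expected format."""


class EmptyInputError(IrimapError, ValueError):
    """An input file or table contains no usable rows."""


class DomainError(IrimapError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ConfigError(IrimapError, ValueError):
    """A configuration value violates its invariants."""
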