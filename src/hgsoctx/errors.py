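"""Exception hierarchy shared across the toolkit."""


class HgsoctxError(Exception):
    """Base class for all toolkit errors."""


class FormatError(HgsoctxError):
    """A file does not conform to its declared format (ragged rows, bad header...)."""


class ValidationError(HgsoctxError):
    """Well-formed input whose content violates a domain invariant."""


class ConfigError(HgsoctxError):
    """An infeasible or out-of-domain configuration value."""
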