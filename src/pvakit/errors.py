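"""Exception hierarchy used across pvakit."""


class PvaError(Exception):
    """Base class for all pvakit errors."""


class FormatError(PvaError):
    """A file or record does not conform to the documented layout."""


class DataError(PvaError):
    """Input data are structurally valid but unusable (empty, too short,
    non-monotone time axis, too many invalid samples, ...)."""


class ConfigError(PvaError):
    """A configuration object is internally inconsistent."""


class ContractError(PvaError):
    """A caller violated a documented precondition."""
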