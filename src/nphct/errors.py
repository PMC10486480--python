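"""Exception hierarchy shared across the toolkit."""


class NphctError(ValueError):
    """Base class for all toolkit errors."""


class ParameterError(NphctError):
    """An argument is outside its documented domain."""


class MeasurementError(NphctError):
    """A radiological measurement is anatomically impossible or out of range."""


class DegenerateInputError(NphctError):
    """Input is structurally valid but empty/degenerate for the requested operation."""


class InconsistencyError(NphctError):
    """Inputs are mutually inconsistent (e.g. rates implying negative counts)."""


class ConfigError(NphctError):
    """A pipeline configuration contains an unknown or invalid key."""
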