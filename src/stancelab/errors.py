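"""Exception hierarchy shared across the package."""


class StancelabError(Exception):
    """Base class for all package errors."""


class ConfigError(StancelabError):
    """Invalid configuration value; the message names the offending field."""


class ParameterError(StancelabError):
    """An argument is outside its valid range (e.g. cutoff at or above Nyquist)."""


class DataError(StancelabError):
    """Input data violate a precondition (NaNs, too-short windows, ...)."""


class ResolutionError(DataError):
    """The sampling rate is too coarse to resolve the requested quantity."""


class GeometryError(StancelabError):
    """Degenerate marker geometry (zero-length or vanishing-projection axes)."""


class GenerationError(StancelabError):
    """Requested synthetic waveform constraints are unsatisfiable."""


class SampleSizeError(StancelabError):
    """Too few observations for the requested statistic."""
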