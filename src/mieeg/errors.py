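"""Exception hierarchy shared across the pipeline."""


class MieegError(Exception):
    """Base class for all package errors."""


class ConfigError(MieegError, ValueError):
    """A configuration field violates its invariant; message names the field."""


class FormatError(MieegError, ValueError):
    """Unknown or malformed file format."""


class LabelError(FormatError):
    """Trial labels missing or unparsable."""


class ChannelMismatchError(FormatError):
    """Channel count does not match the declared channel names."""


class DimensionError(MieegError, ValueError):
    """Array dimensions incompatible with the requested operation."""


class DepthError(MieegError, ValueError):
    """Signal too short for the requested wavelet decomposition depth."""


class NyquistError(ConfigError):
    """Requested analysis frequency at or above the Nyquist limit."""


class ShapeError(MieegError, ValueError):
    """Input shape incompatible with a fitted model or expected layout."""


class TrainingError(MieegError, RuntimeError):
    """Training cannot proceed (e.g. single-class input)."""


class OptimizationError(MieegError, RuntimeError):
    """Metaheuristic search failed (e.g. objective never finite)."""
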