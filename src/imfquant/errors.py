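"""Exception hierarchy used across the pipeline."""


class ImfquantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ImfquantError):
    """Invalid configuration values (counts, window sizes, rates)."""


class FormatError(ImfquantError):
    """Malformed input data (wrong channel count, shape mismatch)."""


class EmptyMaskError(ImfquantError):
    """An operation that requires foreground pixels received none."""


class GenerationError(ImfquantError):
    """Synthetic rendering could not satisfy its target."""


class DegenerateClusteringError(ImfquantError):
    """Fewer distinct colors than requested clusters."""


class ModelStateError(ImfquantError):
    """A model was used before training / loading weights."""


class DataError(ImfquantError):
    """Empty or inconsistent data passed to a training or fitting routine."""


class UndefinedFractionError(ImfquantError):
    """A fat fraction was requested against an empty tissue mask."""


class EffectSizeError(ImfquantError):
    """Effect size undefined (zero pooled SD with unequal means)."""


class FitError(ImfquantError):
    """Mixed-model fitting or degrees-of-freedom computation failed."""
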