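"""Exception types shared across the package."""


class FundusFocusError(Exception):
    """Base class for all package-specific errors."""


class MaskValidationError(FundusFocusError, ValueError):
    """A mask plane contains values other than 0/1, or violates an invariant."""


class ShapeMismatchError(FundusFocusError, ValueError):
    """Arrays that must share a spatial shape do not."""


class FormatError(FundusFocusError, ValueError):
    """An on-disk file is not in the expected format."""


class RegistryLookupError(FundusFocusError, KeyError):
    """A class name is not present in a channel registry."""


class ParameterError(FundusFocusError, ValueError):
    """A scalar parameter is outside its documented range."""


class DegenerateStatsError(FundusFocusError, ValueError):
    """Normalization statistics are degenerate (zero spread)."""


class StratificationError(FundusFocusError, ValueError):
    """Risk stratification is impossible (e.g. all scores identical)."""


class ConfigError(FundusFocusError, ValueError):
    """A pipeline configuration is invalid."""
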