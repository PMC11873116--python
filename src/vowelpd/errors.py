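"""Exception hierarchy shared across the pipeline stages."""


class VowelPDError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(VowelPDError, ValueError):
    """A synthesis / channel / cohort specification violates its invariants."""


class FormatError(VowelPDError, ValueError):
    """An audio file is missing, empty, non-mono or not PCM."""


class DegenerateInputError(VowelPDError, ValueError):
    """Input is silent, unvoiced or otherwise carries no usable signal."""


class TooShortError(VowelPDError, ValueError):
    """Recording shorter than the minimum analyzable duration (1.5 s)."""


class InsufficientCyclesError(VowelPDError, ValueError):
    """Fewer glottal cycles than the perturbation quotients require (12)."""


class ConfigError(VowelPDError, ValueError):
    """Pipeline configuration is invalid or contains unknown keys."""
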