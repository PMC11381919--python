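"""Exception hierarchy for the meafp pipeline."""


class MeafpError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(MeafpError, ValueError):
    """A scalar argument is outside its documented domain."""


class ConfigurationError(MeafpError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


class UnsupportedInputError(MeafpError, ValueError):
    """Input is well formed but outside the supported operating range
    (e.g. sampling rate below 1 kHz)."""


class InvalidWindowError(MeafpError, ValueError):
    """A measurement window falls outside the trace bounds."""


class ClusteringError(MeafpError, ValueError):
    """Beat clustering window is pathological (>= the minimum cycle length)."""


class InsufficientCoverageError(MeafpError, ValueError):
    """Too few electrodes or beats to compute a spatial/rhythm statistic."""


class DegenerateGeometryError(MeafpError, ValueError):
    """Electrode geometry or activation pattern does not admit a plane fit."""


class DesignError(MeafpError, ValueError):
    """Statistical design is singular (e.g. a single genotype)."""


class ConvergenceError(MeafpError, RuntimeError):
    """Mixed-model fit failed to converge."""


class SchemaError(MeafpError, ValueError):
    """A table is missing required columns or metadata."""


class NormalizationError(MeafpError, ValueError):
    """Housekeeping normalisation cannot be computed for a sample."""


class ParseError(MeafpError, ValueError):
    """An on-disk artefact is malformed."""
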