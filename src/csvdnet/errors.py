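"""Exception and warning hierarchy for the connectome pipeline."""


class CsvdnetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CsvdnetError, ValueError):
    """An argument violates a documented precondition."""


class ConfigError(CsvdnetError, ValueError):
    """A configuration object is internally inconsistent."""


class GenerationError(CsvdnetError, RuntimeError):
    """Synthetic-data generation could not satisfy its contract."""


class MatrixValidationError(CsvdnetError, ValueError):
    """A connectivity matrix violates its invariants (asymmetry, NaN, shape...)."""


class EmptyNetworkError(CsvdnetError, ValueError):
    """An operation requiring at least one edge received an edgeless network."""


class DegenerateThresholdError(CsvdnetError, ValueError):
    """A sparsity level retains zero edges."""


class DegenerateEnsembleError(CsvdnetError, RuntimeError):
    """A random-network ensemble yields an unusable normalization constant."""


class DisconnectedNetworkWarning(UserWarning):
    """A thresholded network has unreachable node pairs."""


class NullModelWarning(UserWarning):
    """Edge rewiring stopped short of its target swap count."""


class ThresholdWarning(UserWarning):
    """A sparsity level requested more edges than the matrix provides."""
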