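"""Exception hierarchy for biogaps.

All package errors derive from :class:`BiogapsError` so callers can catch
one base class; the subclasses mirror the failure modes of the pipeline
stages (design construction, calibration, estimation, sampling).
"""


class BiogapsError(Exception):
    """Base class for all biogaps errors."""


class InvalidDesignError(BiogapsError):
    """A simulation or model design is structurally invalid."""


class GenerationError(BiogapsError):
    """Data generation produced non-finite or otherwise invalid values."""


class CalibrationError(BiogapsError):
    """An inclusion-probability intercept cannot hit the target fraction."""


class AlignmentError(BiogapsError):
    """Unit keys of two objects (data vs mask/design) do not align."""


class EstimationError(BiogapsError):
    """An estimator received input it cannot produce an estimate from."""


class WeightingError(BiogapsError):
    """Inverse-probability weights are undefined (non-positive pi)."""


class SubsamplingError(BiogapsError):
    """Balanced subsampling received empty input."""


class SamplerError(BiogapsError):
    """The MCMC sampler failed (e.g. zero acceptance after adaptation)."""


class ConfigError(BiogapsError):
    """An experiment configuration is invalid or contains unknown keys."""
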