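"""Exception hierarchy for grseval.

All package-specific failures derive from :class:`GRSEvalError` so callers can
catch one base class; subclasses distinguish configuration mistakes from data
coding problems, estimation failures, and simulation dead-ends.
"""


class GRSEvalError(Exception):
    """Base class for all grseval errors."""


class ConfigurationError(GRSEvalError, ValueError):
    """Invalid model specification, preset name, or study configuration."""


class CodingError(GRSEvalError, ValueError):
    """Genotype or phenotype values violate the 0/1/2 (or 0/1) coding."""


class RescalingError(GRSEvalError, ValueError):
    """Weight rescaling requested but the weight sum is not positive."""


class EstimationError(GRSEvalError, RuntimeError):
    """Per-locus weight estimation failed (monomorphic locus, separation...)."""

    def __init__(self, message: str, failed_loci: list | None = None):
        super().__init__(message)
        self.failed_loci = failed_loci or []


class SimulationError(GRSEvalError, RuntimeError):
    """A simulator could not produce the requested data (e.g. quota unreachable)."""


class CapacityError(GRSEvalError, ValueError):
    """Exact genotype enumeration requested beyond the supported locus count."""
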