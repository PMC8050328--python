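"""Exception types raised across the package."""


class ReecsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ReecsimError, ValueError):
    """A physical or numerical parameter violates its domain."""


class InvalidStateError(ReecsimError, ValueError):
    """A state variable (e.g. a concentration) is outside its physical range."""


class InfiniteLengthError(ReecsimError, ValueError):
    """The characteristic diffusion-consumption length is infinite (no consumption)."""


class SolverError(ReecsimError, RuntimeError):
    """The time integrator became unstable or produced unphysical values."""


class ProfileError(ReecsimError, ValueError):
    """A radial profile is empty, malformed, or incompatible with the operation."""


class NormalizationError(ProfileError):
    """A normalization reference is zero, missing, or inconsistent."""


class UndefinedFrontError(ProfileError):
    """A front cannot be defined (flat profile, no crossing where one is required)."""


class UndefinedCorrelationError(ProfileError):
    """Pearson correlation is undefined (zero variance or too few paired bins)."""


class ConfigError(ReecsimError, ValueError):
    """A run configuration file is malformed or contains unknown keys."""
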