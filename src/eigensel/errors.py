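"""Exception hierarchy shared across the package."""


class EigenselError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EigenselError, ValueError):
    """An argument or configuration value is outside its valid range."""


class InputError(EigenselError, ValueError):
    """Input data (VCF, metadata, matrices) violate a precondition."""


class SimulationError(EigenselError, RuntimeError):
    """The genotype simulator cannot satisfy its post-conditions."""


class FitError(EigenselError, RuntimeError):
    """A model fit failed to converge or is ill-posed."""
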