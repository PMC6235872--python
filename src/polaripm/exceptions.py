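"""Exception hierarchy for polaripm."""


class PolarIPMError(Exception):
    """Base class for all polaripm errors."""


class InvalidInputError(PolarIPMError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateLitterError(PolarIPMError):
    """Cub survival of zero makes the conditional litter distribution undefined."""


class ImpossibleDataError(PolarIPMError, ValueError):
    """Observed data have probability zero under every latent configuration."""


class InfeasibleMomentsError(PolarIPMError, ValueError):
    """Requested mean/sd pair is outside the Beta family (sd^2 >= mean(1-mean))."""


class StationaryDistributionError(PolarIPMError):
    """The reproductive chain has no unique stationary distribution."""
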