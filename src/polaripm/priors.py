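"""Prior distributions for the integrated model.

Survival of independent bears is well documented across polar bear
subpopulations, so subadult and adult survival get informative Beta priors
moment-matched to published point estimates; breeding probability after
litter loss (``B2``) is weakly identifiable and gets an informative
Beta(2.1, 11.4).  Everything else is vague: Uniform(0, 1) for probabilities,
a flat Dirichlet for the age-zero litter-size simplex, and Uniform(0, N_max)
for initial abundance.  A vague-only switch supports prior-sensitivity runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
from scipy.special import betaln

from .exceptions import InfeasibleMomentsError, InvalidInputError

__all__ = ["moment_match_beta", "PriorSet"]


def moment_match_beta(mean: float, sd: float) -> tuple[float, float]:
    """Beta(alpha, beta) with the requested mean and standard deviation.

    alpha = mean * c, beta = (1 - mean) * c with c = mean(1-mean)/sd^2 - 1.
    """
    if not 0.0 < mean < 1.0:
        raise InvalidInputError(f"mean={mean} must lie strictly in (0, 1)")
    if sd <= 0.0:
        raise InvalidInputError(f"sd={sd} must be positive")
    if sd * sd >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"sd^2={sd * sd:.6g} >= mean(1-mean)={mean * (1 - mean):.6g}: "
            "no Beta distribution has these moments"
        )
    c = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * c, (1.0 - mean) * c


# published survival point estimates (mean, sd on the probability scale)
SURVIVAL_PRIOR_MOMENTS = {
    "phi_SF": (0.89, 0.05),
    "phi_AF": (0.93, 0.02),
    "phi_SM": (0.82, 0.10),
    "phi_AM": (0.89, 0.05),
}

B2_PRIOR = (2.1, 11.4)


@dataclass(frozen=True)
class PriorSet:
    """Beta hyperparameters for the informatively specified parameters."""

    survival_beta: dict = field(default_factory=dict)
    b2_beta: tuple[float, float] = B2_PRIOR
    vague_only: bool = False

    def __post_init__(self) -> None:
        for name, (a, b) in {**self.survival_beta, "B2": self.b2_beta}.items():
            if a <= 0 or b <= 0:
                raise InvalidInputError(f"{name}: Beta hyperparameters must be > 0")

    @classmethod
    def default(cls, vague_only: bool = False) -> "PriorSet":
        betas = {
            name: moment_match_beta(m, s)
            for name, (m, s) in SURVIVAL_PRIOR_MOMENTS.items()
        }
        return cls(survival_beta=betas, vague_only=vague_only)

    def logpdf(self, name: str, value: float) -> float:
        """Log prior density for one survival/breeding parameter.

        Parameters without an informative prior (or all parameters when
        ``vague_only``) are Uniform(0, 1).
        """
        if not 0.0 <= value <= 1.0:
            return -np.inf
        if self.vague_only:
            return 0.0
        if name in self.survival_beta:
            a, b = self.survival_beta[name]
        elif name == "B2":
            a, b = self.b2_beta
        else:
            return 0.0
        if value in (0.0, 1.0):
            return -np.inf
        return (a - 1.0) * math.log(value) + (b - 1.0) * math.log1p(-value) - betaln(a, b)

    def rvs(self, name: str, rng) -> float:
        if not self.vague_only and name in self.survival_beta:
            a, b = self.survival_beta[name]
            return float(rng.beta(a, b))
        if not self.vague_only and name == "B2":
            return float(rng.beta(*self.b2_beta))
        return float(rng.uniform(0.02, 0.98))
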