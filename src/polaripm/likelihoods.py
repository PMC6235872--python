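"""Count-data log-likelihood components of the integrated model."""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln, xlogy

from .exceptions import InvalidInputError

__all__ = ["state_count_loglik", "litter_count_loglik", "wean_count_loglik"]


def state_count_loglik(n: int, N: int, p: float, inside: int) -> float:
    """Binomial log-likelihood of capturing ``n`` of ``N`` bears in a state.

    Success probability is ``p * I_s`` where the indicator ``inside`` is 1
    for inside states: bears outside the study area are uncapturable.
    Returns -inf for impossible data (n > N, or n > 0 with zero capture
    probability).
    """
    if n < 0 or N < 0:
        raise InvalidInputError("counts must be nonnegative")
    pr = p * (1 if inside else 0)
    if not 0.0 <= pr <= 1.0:
        raise InvalidInputError(f"capture probability {pr} outside [0, 1]")
    if n > N:
        return -np.inf
    if pr == 0.0:
        return 0.0 if n == 0 else -np.inf
    return float(stats.binom.logpmf(n, N, pr))


def litter_count_loglik(counts, omega_L1) -> float:
    """Multinomial log-likelihood of the age-one litter-size counts (sizes 1-3)."""
    c = np.asarray(counts, dtype=float)
    w = np.asarray(omega_L1, dtype=float)
    if c.shape != (3,) or np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise InvalidInputError(f"litter counts {counts} invalid")
    if c.sum() == 0:
        return 0.0
    if np.any((w == 0.0) & (c > 0)):
        return -np.inf
    return float(
        gammaln(c.sum() + 1) - gammaln(c + 1).sum() + xlogy(c, w).sum()
    )


def wean_count_loglik(n_wean: int, n_c2: int, W: float) -> float:
    """Binomial log-likelihood of observing ``n_wean`` independent two-year-olds."""
    if n_wean < 0 or n_c2 < 0:
        raise InvalidInputError("counts must be nonnegative")
    if n_wean > n_c2:
        return -np.inf
    if n_c2 == 0:
        return 0.0
    return float(
        gammaln(n_c2 + 1) - gammaln(n_wean + 1) - gammaln(n_c2 - n_wean + 1)
        + xlogy(n_wean, W) + xlogy(n_c2 - n_wean, 1.0 - W)
    )
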