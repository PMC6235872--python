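"""Age-one cubs per adult female: Poisson rate with an adult-female offset.

The number of age-one cubs counted each spring, per adult female counted, is
a productivity metric that integrates cub production and first-year
survival.  Annual cub counts are Poisson with the adult-female count as an
offset; a constant model (log rate = a) is compared with a linear trend
(log rate = a + b * centred year).  Fitting is Bayesian with vague normal
priors; under a flat prior the constant model has a closed-form Gamma
posterior used as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .exceptions import InvalidInputError
from .model import posterior_summary

__all__ = ["TrendData", "C1PerFemaleTrend", "TrendResults"]


@dataclass
class TrendData:
    """Per sampled year: number of age-one cubs and number of adult females."""

    years: np.ndarray
    n_c1: np.ndarray
    n_af: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.n_c1 = np.asarray(self.n_c1, dtype=float)
        self.n_af = np.asarray(self.n_af, dtype=float)
        if not (len(self.years) == len(self.n_c1) == len(self.n_af)):
            raise InvalidInputError("trend data columns have unequal lengths")
        if np.any(self.n_c1 < 0):
            raise InvalidInputError("cub counts must be nonnegative")
        if np.any(self.n_af <= 0):
            raise InvalidInputError(
                "adult-female offsets must be positive in included years"
            )

    @classmethod
    def from_count_data(cls, counts) -> "TrendData":
        """Collapse IPM count tables: total C1s and adult females per year.

        C1 totals are litter-size-weighted litter counts; the offset sums
        captures over all adult-female states.
        """
        years = counts.years[counts.sampled.loc[counts.years].to_numpy()]
        sizes = np.array([1, 2, 3])
        n_c1 = (counts.litter_counts.loc[years] * sizes).sum(axis=1).to_numpy()
        af_cols = [
            c for c in counts.state_counts.columns
            if c.startswith("F:AF")
        ]
        n_af = counts.state_counts.loc[years, af_cols].sum(axis=1).to_numpy()
        keep = n_af > 0
        return cls(years=years[keep], n_c1=n_c1[keep], n_af=n_af[keep])


@dataclass
class TrendResults:
    """Posterior summaries for the fitted rate model."""

    model_kind: str
    rate: tuple            # (mode, q2.5, q97.5) of C1s per adult female
    slope: tuple | None    # per-year log-rate slope, linear model only
    dic: float
    draws: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        rows = {"rate": self.rate}
        if self.slope is not None:
            rows["slope"] = self.slope
        return pd.DataFrame(rows, index=["mode", "q2.5", "q97.5"]).T


class C1PerFemaleTrend:
    """Bayesian Poisson-offset model for cubs per adult female."""

    def __init__(self, data: TrendData):
        self.data = data
        self._t = data.years - data.years.mean()  # centred at the midpoint

    def _loglik(self, a: float, b: float) -> float:
        log_mu = a + b * self._t + np.log(self.data.n_af)
        mu = np.exp(log_mu)
        return float(np.sum(self.data.n_c1 * log_mu - mu
                            - gammaln(self.data.n_c1 + 1)))

    def _logpost(self, theta: np.ndarray, linear: bool) -> float:
        a = theta[0]
        b = theta[1] if linear else 0.0
        lp = stats.norm.logpdf(a, 0.0, 10.0)
        if linear:
            lp += stats.norm.logpdf(b, 0.0, 10.0)
        return float(lp + self._loglik(a, b))

    def fit(self, kind: str = "constant", draws: int = 1500, tune: int = 500,
            walkers: int = 16, seed: int | None = None) -> TrendResults:
        import emcee

        if kind not in ("constant", "linear"):
            raise InvalidInputError(f"unknown model kind {kind!r}")
        linear = kind == "linear"
        if linear and len(self.data.years) < 2:
            raise InvalidInputError("linear trend needs at least 2 years")
        ndim = 2 if linear else 1
        rng = np.random.default_rng(seed)
        raw = self.data.n_c1.sum() / self.data.n_af.sum()
        a0 = np.log(max(raw, 1e-3))
        p0 = a0 + 0.1 * rng.standard_normal((walkers, 1))
        if linear:
            p0 = np.hstack([p0, 0.02 * rng.standard_normal((walkers, 1))])
        sampler = emcee.EnsembleSampler(
            walkers, ndim, self._logpost, args=(linear,)
        )
        sampler.random_state = np.random.RandomState(rng.integers(2**31)).get_state()
        state = sampler.run_mcmc(p0, tune, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, draws, progress=False)
        flat = sampler.get_chain(flat=True)
        rate_draws = np.exp(flat[:, 0])
        cols = {"a": flat[:, 0], "rate": rate_draws}
        slope = None
        if linear:
            cols["b"] = flat[:, 1]
            slope = posterior_summary(flat[:, 1])
        df = pd.DataFrame(cols)
        # DIC = D(theta_bar) + 2 p_D with D = -2 log L
        dev = -2.0 * np.array(
            [self._loglik(a, (b if linear else 0.0))
             for a, b in zip(flat[:, 0], flat[:, 1] if linear else np.zeros(len(flat)))]
        )
        mean_theta = flat.mean(axis=0)
        d_hat = -2.0 * self._loglik(mean_theta[0],
                                    mean_theta[1] if linear else 0.0)
        dic = float(d_hat + 2.0 * (dev.mean() - d_hat))
        return TrendResults(
            model_kind=kind, rate=posterior_summary(rate_draws),
            slope=slope, dic=dic, draws=df,
        )

    def constant_rate_conjugate(self):
        """Closed-form Gamma posterior of the constant rate under a flat prior.

        With a flat prior on the rate itself, ``rate | data ~ Gamma(sum C1 + 1,
        rate=sum AF)``; returned as a frozen scipy distribution.
        """
        return stats.gamma(
            a=self.data.n_c1.sum() + 1.0, scale=1.0 / self.data.n_af.sum()
        )
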