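"""Closure-corrected density and habitat-weighted abundance extrapolation.

Study-area abundance refers to bears that used a localised sampling area, so
converting it to a density requires a geographic-closure correction: the mean
proportion ``q_hat`` of collared females' spring use areas lying inside the
core sampling area.  Density is then spread over the full subpopulation
boundary in proportion to a habitat-quality metric ``h_x`` on a 25 x 25 km
grid (1:1 habitat-to-density relationship).  Because females with age-zero
cubs den away from the sampling area, extrapolation runs on an abundance that
excludes them, and mothers with age-zero litters are added back afterwards
from the stationary composition of the fitted reproductive chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import Point

from .exceptions import InvalidInputError, StationaryDistributionError
from .lifecycle import (
    LitterModel,
    VitalRates,
    joint_expectation_matrix,
    litter_thinning,
    stable_stage_distribution,
)
from .model import PARAM_NAMES, _JOINT_LABELS, posterior_summary

__all__ = [
    "UseAreas",
    "HabitatGrid",
    "ExtrapolationResult",
    "compute_qhat",
    "density_from_study",
    "extrapolate_abundance",
    "stationary_reproductive_distribution",
    "afc0_addback_factor",
    "add_dependent_c0",
    "removal_rate_report",
    "DensityExtrapolation",
]

DEFAULT_SAMPLING_AREA_KM2 = 25_000.0
REPRO_CLASSES = ("AFNC", "AFC0", "AFC1", "AFC2")


@dataclass
class UseAreas:
    """Per-female proportions of spring use inside the core sampling area."""

    proportions: pd.Series
    area_sampling_km2: float = DEFAULT_SAMPLING_AREA_KM2

    def __post_init__(self) -> None:
        p = self.proportions.astype(float)
        if ((p < 0) | (p > 1)).any():
            raise InvalidInputError("use-area proportions must lie in [0, 1]")
        if self.area_sampling_km2 <= 0:
            raise InvalidInputError("sampling area must be positive")
        self.proportions = p

    @property
    def qhat(self) -> float:
        """Unweighted mean proportion across females."""
        return float(self.proportions.mean())

    def bootstrap_qhat(self, rng) -> float:
        """q_hat recomputed on a resample (with replacement) of females."""
        idx = rng.integers(0, len(self.proportions), len(self.proportions))
        return float(self.proportions.iloc[idx].mean())


@dataclass
class HabitatGrid:
    """Habitat-quality cells with sampling-area and boundary masks.

    ``cells`` columns: ``cell_id``, ``h`` (relative probability of use,
    >= 0), ``in_sampling`` and ``in_cs`` (0/1 masks).  Sampling cells must be
    a subset of subpopulation-boundary cells and carry positive total
    habitat.  Cell size is 25 x 25 km by convention.
    """

    cells: pd.DataFrame = field(repr=False)
    cell_area_km2: float = 625.0

    def __post_init__(self) -> None:
        required = {"cell_id", "h", "in_sampling", "in_cs"}
        missing = required - set(self.cells.columns)
        if missing:
            raise InvalidInputError(f"habitat grid missing columns {sorted(missing)}")
        c = self.cells
        if (c["h"] < 0).any():
            raise InvalidInputError("habitat values must be nonnegative")
        if (c["in_sampling"].astype(bool) & ~c["in_cs"].astype(bool)).any():
            raise InvalidInputError("sampling cells must lie within the CS boundary")
        if self.h_sum_sampling <= 0:
            raise InvalidInputError("zero habitat mass in sampling cells")

    @property
    def h_sum_sampling(self) -> float:
        m = self.cells["in_sampling"].astype(bool)
        return float(self.cells.loc[m, "h"].sum())

    @property
    def h_sum_cs(self) -> float:
        m = self.cells["in_cs"].astype(bool)
        return float(self.cells.loc[m, "h"].sum())

    @property
    def boundary_area_km2(self) -> float:
        return float(self.cells["in_cs"].astype(bool).sum() * self.cell_area_km2)

    @classmethod
    def read(cls, path, **kw) -> "HabitatGrid":
        return cls(pd.read_csv(path), **kw)

    def write(self, path) -> None:
        self.cells.to_csv(path, index=False)


def compute_qhat(
    locations: pd.DataFrame,
    core_polygon,
    area_sampling_km2: float = DEFAULT_SAMPLING_AREA_KM2,
) -> UseAreas:
    """Per-female proportion of spring locations inside the core polygon.

    ``locations``: columns ``id``, ``timestamp``, ``x``, ``y`` in a projected
    metric coordinate system; ``core_polygon`` a shapely polygon or WKT
    string.  Females contributing no locations are excluded with a warning.
    """
    if isinstance(core_polygon, str):
        core_polygon = shapely_wkt.loads(core_polygon)
    props = {}
    for ind, grp in locations.groupby("id", sort=False):
        if len(grp) == 0:
            warnings.warn(f"female {ind!r} has no spring locations; excluded",
                          stacklevel=2)
            continue
        inside = np.fromiter(
            (core_polygon.covers(Point(x, y))
             for x, y in zip(grp["x"], grp["y"])),
            dtype=bool, count=len(grp),
        )
        props[ind] = float(inside.mean())
    if not props:
        raise InvalidInputError("no female contributed any spring location")
    return UseAreas(pd.Series(props), area_sampling_km2)


def density_from_study(n_bar_study, qhat, area_sampling_km2: float):
    """Closure-corrected density: ``N_bar_study * q_hat / A_sampling``.

    Accepts scalars or per-draw arrays (applied elementwise).
    """
    if area_sampling_km2 <= 0:
        raise InvalidInputError("sampling area must be positive")
    return np.asarray(n_bar_study, dtype=float) * np.asarray(qhat, dtype=float) / (
        area_sampling_km2
    )


def extrapolate_abundance(d_star_sampling, area_sampling_km2, grid: HabitatGrid):
    """Habitat-weighted extrapolation to the subpopulation boundary.

    ``N*_CS = (D* x A_sampling) x sum_CS h / sum_sampling h``; invariant to
    positive rescaling of h.
    """
    return (
        np.asarray(d_star_sampling, dtype=float)
        * area_sampling_km2
        * grid.h_sum_cs
        / grid.h_sum_sampling
    )


def stationary_reproductive_distribution(
    rates: VitalRates, litter: LitterModel | None = None
) -> pd.Series:
    """Stationary distribution of the adult-female reproductive chain.

    The chain is over (AFNC, AFC0, AFC1, AFC2) with transitions conditional
    on survival; movement and death are integrated out.  Raises if the chain
    has no unique stationary distribution.
    """
    if litter is None:
        litter = litter_thinning(rates.omega_L0, rates.phi_C0, rates.phi_C1)
    B1, B2, W = rates.B1, rates.B2, rates.W
    pL0, pL1 = litter.phi_L0, litter.phi_L1
    P = np.zeros((4, 4))  # [source, dest]
    P[0] = [1 - B1, B1, 0, 0]
    P[1] = [(1 - pL0) * (1 - B2), (1 - pL0) * B2, pL0, 0]
    P[2] = [pL1 * W + (1 - pL1) * (1 - B2), (1 - pL1) * B2, 0, pL1 * (1 - W)]
    P[3] = [1 - B1, B1, 0, 0]
    vals, vecs = np.linalg.eig(P.T)
    close = np.isclose(vals, 1.0, atol=1e-9)
    if close.sum() == 0:
        raise StationaryDistributionError("no unit eigenvalue in reproductive chain")
    if close.sum() > 1:
        raise StationaryDistributionError(
            "reproductive chain is reducible with multiple stationary "
            "distributions"
        )
    v = vecs[:, close].real.ravel()
    v = np.abs(v)
    return pd.Series(v / v.sum(), index=list(REPRO_CLASSES))


def afc0_addback_factor(rates: VitalRates, litter: LitterModel | None = None) -> float:
    """Bears added per extrapolated bear to restore AFC0 mothers and C0 cubs.

    From the stable stage structure, the adult-female share of the
    AFC0-excluded population determines the implied number of AFC0 mothers
    via the stationary reproductive-chain fraction ``pi``:
    ``N_AFC0 = N_AF_excl * pi / (1 - pi)``, each mother carrying ``l_L0``
    age-zero cubs.
    """
    if litter is None:
        litter = litter_thinning(rates.omega_L0, rates.phi_C0, rates.phi_C1)
    pi = float(stationary_reproductive_distribution(rates, litter)["AFC0"])
    if pi >= 1.0:
        raise StationaryDistributionError("degenerate chain: all mass on AFC0")
    A, labels = joint_expectation_matrix(rates, litter)
    _, stable = stable_stage_distribution(A)
    stable = pd.Series(stable, index=labels)

    def mass(classes):
        return float(
            sum(stable[f"F:{c}_{loc}"] for c in classes for loc in ("in", "out"))
        )

    af_excl = mass(("AFNC", "AFC1", "AFC2"))
    # composition of the AFC0-excluded extrapolated total: independent bears
    # (all live states except AFC0) plus dependent age-one cubs
    total_excl = float(stable.sum()) - mass(("AFC0",)) + litter.l_L1 * mass(("AFC1",))
    n_afc0_per_unit = (af_excl / total_excl) * pi / (1.0 - pi)
    return n_afc0_per_unit * (1.0 + litter.l_L0)


def add_dependent_c0(n_star_cs, rates: VitalRates,
                     litter: LitterModel | None = None):
    """Add AFC0 mothers and their age-zero cubs back to an extrapolated total."""
    return np.asarray(n_star_cs, dtype=float) * (
        1.0 + afc0_addback_factor(rates, litter)
    )


def removal_rate_report(removals: float, abundance) -> dict:
    """Annual human-caused removals as a percentage of abundance.

    ``abundance`` may be a scalar, an array of posterior draws, or a
    (point, low, high) triple; low abundance gives the high removal rate.
    """
    if removals < 0:
        raise InvalidInputError("removals must be nonnegative")
    ab = np.atleast_1d(np.asarray(abundance, dtype=float))
    if np.any(ab <= 0):
        raise InvalidInputError("abundance must be positive")
    rate = 100.0 * removals / ab
    if ab.size == 1:
        return {"point_pct": float(rate[0])}
    if ab.size == 3:
        point, lo, hi = ab
        return {
            "point_pct": float(100.0 * removals / point),
            "low_pct": float(100.0 * removals / hi),
            "high_pct": float(100.0 * removals / lo),
        }
    mode, lo, hi = posterior_summary(ab)
    return {
        "point_pct": float(100.0 * removals / mode),
        "low_pct": float(100.0 * removals / hi),
        "high_pct": float(100.0 * removals / lo),
    }


@dataclass
class ExtrapolationResult:
    """Summaries (mode, 2.5%, 97.5%) of the extrapolation pipeline."""

    d_sampling: tuple
    d_star_sampling: tuple
    n_star_cs: tuple
    n_cs: tuple
    qhat: float
    boundary_density: tuple
    draws: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        rows = {
            "D_sampling": self.d_sampling,
            "D_star_sampling": self.d_star_sampling,
            "N_star_CS": self.n_star_cs,
            "N_CS": self.n_cs,
            "D_CS_boundary": self.boundary_density,
        }
        return pd.DataFrame(rows, index=["mode", "q2.5", "q97.5"]).T


class DensityExtrapolation:
    """Per-posterior-draw extrapolation with bootstrap closure uncertainty.

    For each posterior draw the pipeline recomputes study-area abundance with
    and without AFC0 mothers and their cubs, pairs it with a bootstrap
    resample of the per-female use-area proportions, extrapolates over the
    habitat grid, and adds AFC0/C0 back from the draw's own reproductive
    chain.  Credible intervals are empirical quantiles over draws.
    """

    def __init__(self, results, use_areas: UseAreas, grid: HabitatGrid):
        self.results = results
        self.use_areas = use_areas
        self.grid = grid

    def _per_draw(self, i: int, qhat: float):
        res = self.results
        model = res.model
        rates = res.rates_at(i)
        litter = litter_thinning(rates.omega_L0, rates.phi_C0, rates.phi_C1)
        n_bar = float(res.draws["N_bar_study"].iloc[i])
        # AFC0-excluded study abundance: drop AFC0 mothers and their C0s
        theta = res.draws.iloc[i][PARAM_NAMES].to_numpy(float)
        traj = model._trajectory(rates, litter, float(theta[-1]))
        afc0_in = traj[:, _JOINT_LABELS.index("F:AFC0_in")]
        excl = (1.0 + litter.l_L0) * afc0_in[model.sampling_mask].mean()
        n_bar_star = n_bar - excl
        A = self.use_areas.area_sampling_km2
        d = float(density_from_study(n_bar, qhat, A))
        d_star = float(density_from_study(n_bar_star, qhat, A))
        n_star = float(extrapolate_abundance(d_star, A, self.grid))
        n_cs = float(add_dependent_c0(n_star, rates, litter))
        return d, d_star, n_star, n_cs

    def run(self, seed: int | None = None, max_draws: int = 2000) -> ExtrapolationResult:
        rng = np.random.default_rng(seed)
        n = min(self.results.n_draws, max_draws)
        idx = rng.choice(self.results.n_draws, size=n, replace=False)
        rows = np.empty((n, 4))
        for k, i in enumerate(idx):
            q_b = self.use_areas.bootstrap_qhat(rng)
            rows[k] = self._per_draw(int(i), q_b)
        draws = pd.DataFrame(
            rows, columns=["d_sampling", "d_star_sampling", "n_star_cs", "n_cs"]
        )
        bd = draws["n_cs"] / self.grid.boundary_area_km2
        return ExtrapolationResult(
            d_sampling=posterior_summary(draws["d_sampling"]),
            d_star_sampling=posterior_summary(draws["d_star_sampling"]),
            n_star_cs=posterior_summary(draws["n_star_cs"]),
            n_cs=posterior_summary(draws["n_cs"]),
            qhat=self.use_areas.qhat,
            boundary_density=posterior_summary(bd),
            draws=draws,
        )

    def bootstrap_se(self, n_draws: int, n_boot: int = 100,
                     seed: int | None = None) -> float:
        """Bootstrap standard error of mean N_CS using ``n_draws`` draws."""
        rng = np.random.default_rng(seed)
        n_draws = min(n_draws, self.results.n_draws)
        idx = rng.choice(self.results.n_draws, size=n_draws, replace=False)
        vals = np.array(
            [self._per_draw(int(i), self.use_areas.qhat)[3] for i in idx]
        )
        means = np.array(
            [vals[rng.integers(0, n_draws, n_draws)].mean() for _ in range(n_boot)]
        )
        return float(means.std(ddof=1))
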