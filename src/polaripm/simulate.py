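"""Model-consistent synthetic data: truth, observations, recovery experiments.

Generates complete datasets of the four primary data types (state-specific
capture counts, age-one litter-size counts, dependent/independent
two-year-old counts, and capture/telemetry histories) from the package's own
generative structure: individual-based multinomial life-cycle projection,
Bernoulli captures of bears inside the study area, collar deployment on
captured adult females with geometric collar failure, and event emission per
the multievent observation model.  Default scenario sizes emulate the
Chukchi Sea study design: a 9-year span with 7 sampling years (two skipped),
roughly 20 new captures per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .data import CaptureData, CountData
from .exceptions import InvalidInputError
from .lifecycle import (
    FEMALE,
    MALE,
    FEMALE_STATES,
    MALE_STATES,
    VitalRates,
    _positive_binomial_rvs,
    _wean_share_given_afnc,
    build_transition_matrix,
    joint_expectation_matrix,
    litter_thinning,
    stable_stage_distribution,
)
from .model import _JOINT_LABELS, REPORTED_PARAMS, IPMModel
from .priors import PriorSet

__all__ = [
    "SimulationScenario",
    "Truth",
    "SyntheticBundle",
    "simulate_truth",
    "observe",
    "simulate_bundle",
    "synthetic_extrapolation_inputs",
    "recovery_experiment",
]

_ADULT_F = {"AFNC", "AFC0", "AFC1", "AFC2"}


@dataclass(frozen=True)
class SimulationScenario:
    """Generating parameters and study design for one synthetic dataset."""

    rates: VitalRates
    initial_female: tuple
    initial_male: tuple
    start_year: int = 2008
    n_years: int = 9
    skip_years: tuple = (2012, 2014)
    collar_prob: float = 0.9
    collar_fail: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise InvalidInputError("scenario needs at least 2 years")
        for name in ("collar_prob", "collar_fail"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name}={v} not a probability")
        object.__setattr__(
            self, "initial_female", tuple(int(x) for x in self.initial_female)
        )
        object.__setattr__(
            self, "initial_male", tuple(int(x) for x in self.initial_male)
        )

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    @property
    def sampled(self) -> pd.Series:
        return pd.Series(
            [int(y) not in set(self.skip_years) for y in self.years],
            index=self.years,
        )

    @classmethod
    def default(
        cls, seed: int = 0, n_per_sex: int = 300, rates: VitalRates | None = None,
        **kw,
    ) -> "SimulationScenario":
        """Chukchi-like scenario: point-estimate rates, stable stage start."""
        rates = rates if rates is not None else VitalRates.chukchi_modes()
        litter = litter_thinning(rates.omega_L0, rates.phi_C0, rates.phi_C1)
        A, labels = joint_expectation_matrix(rates, litter)
        _, stable = stable_stage_distribution(A)
        stable = pd.Series(stable, index=labels)
        nf = FEMALE_STATES.n_states
        init_f = np.zeros(nf, dtype=int)
        for i, s in enumerate(FEMALE_STATES.states[:-1]):
            w = stable[f"F:{s}"] / stable[[f"F:{t}" for t in FEMALE_STATES.states[:-1]]].sum()
            init_f[i] = int(round(n_per_sex * w))
        init_m = np.zeros(MALE_STATES.n_states, dtype=int)
        for i, s in enumerate(MALE_STATES.states[:-1]):
            w = stable[f"M:{s}"] / stable[[f"M:{t}" for t in MALE_STATES.states[:-1]]].sum()
            init_m[i] = int(round(n_per_sex * w))
        return cls(rates=rates, initial_female=tuple(init_f),
                   initial_male=tuple(init_m), seed=seed, **kw)

    def to_dict(self) -> dict:
        d = {
            "rates": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in vars(self.rates).items()},
            "initial_female": list(self.initial_female),
            "initial_male": list(self.initial_male),
            "start_year": self.start_year,
            "n_years": self.n_years,
            "skip_years": list(self.skip_years),
            "collar_prob": self.collar_prob,
            "collar_fail": self.collar_fail,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        rates = d["rates"]
        rates = VitalRates(**{k: (tuple(v) if isinstance(v, list) else v)
                              for k, v in rates.items()})
        return cls(
            rates=rates,
            initial_female=tuple(d["initial_female"]),
            initial_male=tuple(d["initial_male"]),
            start_year=int(d["start_year"]), n_years=int(d["n_years"]),
            skip_years=tuple(d["skip_years"]),
            collar_prob=float(d["collar_prob"]),
            collar_fail=float(d["collar_fail"]), seed=int(d["seed"]),
        )


@dataclass
class Truth:
    """Latent truth: individual state paths and per-state abundance tables.

    ``states[sex]``: (n_individuals, n_years) int array of state indices,
    -1 before an individual exists.  ``abundance``: DataFrame year x joint
    live-state labels.  ``n_study``: Series of study-area abundance per year
    (inside bears plus expected dependent cubs).
    """

    scenario: SimulationScenario
    states: dict = field(repr=False)
    abundance: pd.DataFrame = field(repr=False)
    n_study: pd.Series = field(repr=False)
    extinct: bool = False


def simulate_truth(scenario: SimulationScenario) -> Truth:
    """Individual-based multinomial projection of the full population."""
    rng = np.random.default_rng(scenario.seed)
    rates = scenario.rates
    litter = litter_thinning(rates.omega_L0, rates.phi_C0, rates.phi_C1)
    thetas = {
        FEMALE: build_transition_matrix(FEMALE, rates, litter).theta,
        MALE: build_transition_matrix(MALE, rates, litter).theta,
    }
    spaces = {FEMALE: FEMALE_STATES, MALE: MALE_STATES}
    T = scenario.n_years
    paths = {FEMALE: [], MALE: []}
    for sex, init in ((FEMALE, scenario.initial_female), (MALE, scenario.initial_male)):
        for idx, count in enumerate(init):
            for _ in range(count):
                row = -np.ones(T, dtype=int)
                row[0] = idx
                paths[sex].append(row)

    wean_share = _wean_share_given_afnc(litter, rates)
    fs = FEMALE_STATES
    afc1 = {fs.index("AFC1_in"): "in", fs.index("AFC1_out"): "out"}
    afc2_of = {"in": fs.index("AFC2_in"), "out": fs.index("AFC2_out")}
    afnc_of = {"in": fs.index("AFNC_in"), "out": fs.index("AFNC_out")}
    for t in range(T - 1):
        recruits = {"in": 0, "out": 0}
        for sex in (FEMALE, MALE):
            space, theta = spaces[sex], thetas[sex]
            for row in paths[sex]:
                s = row[t]
                if s < 0:
                    continue
                dest = int(rng.choice(space.n_states, p=theta[:, s]))
                row[t + 1] = dest
                if sex == FEMALE and s in afc1:
                    loc = space.location_of(dest)
                    if loc == "dead":
                        continue
                    survived = dest == afc2_of[loc] or (
                        dest == afnc_of[loc] and rng.random() < wean_share
                    )
                    if survived:
                        size = int(rng.choice([1, 2, 3],
                                              p=np.asarray(litter.omega_L1)))
                        n_rec = int(_positive_binomial_rvs(
                            np.array([size]), rates.phi_C1, rng)[0])
                        recruits[loc] += n_rec
        for loc, n_rec in recruits.items():
            for _ in range(n_rec):
                sex = FEMALE if rng.random() < 0.5 else MALE
                row = -np.ones(T, dtype=int)
                row[t + 1] = spaces[sex].index(
                    f"{'F2Y' if sex == FEMALE else 'M2Y'}_{loc}"
                )
                paths[sex].append(row)

    states = {sex: (np.array(paths[sex]) if paths[sex]
                    else np.empty((0, T), dtype=int))
              for sex in (FEMALE, MALE)}
    abundance = pd.DataFrame(0, index=scenario.years, columns=_JOINT_LABELS)
    for sex, prefix in ((FEMALE, "F"), (MALE, "M")):
        space = spaces[sex]
        for t, year in enumerate(scenario.years):
            col = states[sex][:, t] if len(states[sex]) else np.array([], int)
            for idx in range(space.dead_index):
                abundance.loc[year, f"{prefix}:{space.states[idx]}"] = int(
                    (col == idx).sum()
                )
    inside_cols = [c for c in _JOINT_LABELS if c.endswith("_in")]
    n_study = (
        abundance[inside_cols].sum(axis=1)
        + litter.l_L0 * abundance["F:AFC0_in"]
        + litter.l_L1 * abundance["F:AFC1_in"]
    )
    extinct = bool(abundance.loc[scenario.years[-1]].sum() == 0)
    return Truth(scenario=scenario, states=states, abundance=abundance,
                 n_study=n_study, extinct=extinct)


def observe(truth: Truth, scenario: SimulationScenario | None = None,
            rng=None) -> tuple[CountData, CaptureData]:
    """Apply the observation model to latent truth.

    Captures are Bernoulli(p) for inside bears in sampling years; captured
    adult females are collared with probability ``collar_prob`` and collars
    fail each subsequent year with probability ``collar_fail``; telemetry
    events follow the emission model; age-one litter sizes are drawn from
    ``omega_L1`` at capture of AFC1 mothers; observed two-year-olds wean with
    probability ``W``.
    """
    scenario = scenario if scenario is not None else truth.scenario
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 10_000_019)
    rates = scenario.rates
    litter = litter_thinning(rates.omega_L0, rates.phi_C0, rates.phi_C1)
    sampled = scenario.sampled.to_numpy()
    years = scenario.years
    counts = CountData.empty(years, sampled)
    spaces = {FEMALE: FEMALE_STATES, MALE: MALE_STATES}
    rows = []
    for sex, prefix in ((FEMALE, "F"), (MALE, "M")):
        space = spaces[sex]
        arr = truth.states[sex]
        for i in range(len(arr)):
            first_t = None
            collared = False
            for t in range(scenario.n_years):
                s = arr[i, t]
                year = int(years[t])
                alive = 0 <= s < space.dead_index
                inside = alive and space.is_inside(s)
                cls = space.class_of(s) if alive else None
                # collar failure applies at the start of each new year
                if collared and rng.random() < scenario.collar_fail:
                    collared = False
                captured = bool(
                    sampled[t] and inside and rng.random() < rates.p
                )
                if captured:
                    counts.state_counts.loc[year, f"{prefix}:{space.states[s]}"] += 1
                    if cls == "AFC1":
                        size = int(rng.choice([1, 2, 3],
                                              p=np.asarray(litter.omega_L1)))
                        counts.litter_counts.loc[year, size] += 1
                    if cls in ("F2Y", "M2Y"):
                        counts.c2_counts.loc[year, "n_c2"] += 1
                        if rng.random() < rates.W:
                            counts.c2_counts.loc[year, "n_wean_c2"] += 1
                event = None
                if first_t is None:
                    if captured:
                        first_t = t
                        event = f"C:{cls}"
                else:
                    if captured:
                        event = f"C:{cls}"
                    elif collared and alive:
                        if rng.random() < rates.delta:
                            event = f"T:{space.states[s]}"
                        else:
                            event = "TI?" if inside else "TO?"
                    else:
                        event = "0"
                if event is not None:
                    # collar status is a deployment/failure record, known
                    # regardless of whether the bear is still alive
                    rows.append(
                        {"id": f"{prefix}{i:04d}", "sex": sex, "year": year,
                         "event_code": event,
                         "collar_active": int(collared and sex == FEMALE)}
                    )
                if captured and sex == FEMALE and cls in _ADULT_F:
                    if rng.random() < scenario.collar_prob:
                        collared = True
    captures = (
        CaptureData(pd.DataFrame(rows)) if rows else CaptureData.empty()
    )
    counts.validate()
    return counts, captures


@dataclass
class SyntheticBundle:
    """Truth plus the observation datasets derived from the same realisation."""

    scenario: SimulationScenario
    truth: Truth = field(repr=False)
    counts: CountData = field(repr=False)
    captures: CaptureData = field(repr=False)

    def write(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.counts.write(directory)
        self.captures.write(directory / "captures.csv")
        self.truth.abundance.to_csv(directory / "truth_abundance.csv")
        self.truth.n_study.rename("n_study").to_csv(directory / "truth_n_study.csv")
        with open(directory / "scenario.yaml", "w") as fh:
            yaml.safe_dump(self.scenario.to_dict(), fh)

    @classmethod
    def read_observations(cls, directory):
        """(CountData, CaptureData, SimulationScenario) from a bundle directory."""
        from pathlib import Path

        directory = Path(directory)
        counts = CountData.read(directory)
        captures = CaptureData.read(directory / "captures.csv")
        with open(directory / "scenario.yaml") as fh:
            scenario = SimulationScenario.from_dict(yaml.safe_load(fh))
        return counts, captures, scenario


def simulate_bundle(scenario: SimulationScenario) -> SyntheticBundle:
    truth = simulate_truth(scenario)
    counts, captures = observe(truth, scenario)
    return SyntheticBundle(scenario=scenario, truth=truth, counts=counts,
                           captures=captures)


def synthetic_extrapolation_inputs(
    n_females: int = 30,
    n_locations: int = 40,
    seed: int = 0,
    grid_side: int = 30,
    target_q: float = 0.25,
):
    """Synthetic telemetry locations, core polygon and habitat grid.

    Coordinates are km in an arbitrary projected system.  The core sampling
    polygon is a square of 25,000 km^2; female activity centres scatter
    around it so the mean inside proportion is near ``target_q``; the habitat
    grid (25-km cells, ``grid_side`` x ``grid_side``) has smoothly varying
    quality peaking near the core area.  Returns (locations DataFrame,
    polygon WKT, HabitatGrid).
    """
    from shapely.geometry import box

    from .extrapolation import HabitatGrid

    rng = np.random.default_rng(seed)
    side = np.sqrt(25_000.0)
    core = box(0.0, 0.0, side, side)
    # scatter chosen so that a female's gaussian use area overlaps the core
    # by roughly target_q on average
    spread = side * (1.0 / np.sqrt(target_q) - 1.0) / 2.0
    rows = []
    for i in range(n_females):
        cx, cy = rng.uniform(-spread, side + spread, size=2)
        xs = rng.normal(cx, side / 3.0, n_locations)
        ys = rng.normal(cy, side / 3.0, n_locations)
        for k in range(n_locations):
            rows.append({"id": f"AF{i:03d}", "timestamp": f"2010-04-{k % 28 + 1:02d}",
                         "x": xs[k], "y": ys[k]})
    locations = pd.DataFrame(rows)

    cell = 25.0
    half = grid_side // 2
    cells = []
    cx0, cy0 = side / 2.0, side / 2.0
    for ix in range(-half, grid_side - half):
        for iy in range(-half, grid_side - half):
            x0, y0 = ix * cell, iy * cell
            centre = (x0 + cell / 2.0, y0 + cell / 2.0)
            dist = np.hypot(centre[0] - cx0, centre[1] - cy0)
            h = np.exp(-dist / 400.0) * rng.lognormal(0.0, 0.25)
            in_sampling = int(0.0 <= x0 and x0 + cell <= side
                              and 0.0 <= y0 and y0 + cell <= side)
            cells.append({"cell_id": f"c{ix}_{iy}", "h": h,
                          "in_sampling": in_sampling, "in_cs": 1})
    grid = HabitatGrid(pd.DataFrame(cells))
    return locations, core.wkt, grid


def recovery_experiment(
    scenario: SimulationScenario,
    replicates: int,
    priors: PriorSet | None = None,
    fit_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, int]:
    """Simulate-fit cycles: per-parameter 95% CRI coverage and mode bias.

    Returns (table, n_flagged) where ``table`` has one row per reported
    parameter with columns ``truth``, ``coverage`` and ``mean_bias``;
    ``n_flagged`` counts replicates whose sampler diagnostics failed
    (their draws are still included, but reported separately).
    """
    if replicates < 1:
        raise InvalidInputError("need at least one replicate")
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("seed", scenario.seed)
    rates = scenario.rates
    litter = litter_thinning(rates.omega_L0, rates.phi_C0, rates.phi_C1)
    truth_vals = {name: getattr(rates, name)
                  for name in [*REPORTED_PARAMS, "p", "delta"]
                  if hasattr(rates, name)}
    truth_vals["l_L0"] = litter.l_L0
    truth_vals["l_L1"] = litter.l_L1
    covered = {k: [] for k in truth_vals}
    bias = {k: [] for k in truth_vals}
    n_flagged = 0
    for r in range(replicates):
        rep = replace(scenario, seed=scenario.seed + 1000 * (r + 1))
        bundle = simulate_bundle(rep)
        model = IPMModel(bundle.counts, bundle.captures, priors=priors)
        kw = dict(fit_kwargs)
        kw["seed"] = fit_kwargs["seed"] + r
        res = model.fit(**kw)
        if not res.converged:
            n_flagged += 1
        summ = res.summary(list(truth_vals))
        for name, tv in truth_vals.items():
            lo, hi = summ.loc[name, "q2.5"], summ.loc[name, "q97.5"]
            covered[name].append(lo <= tv <= hi)
            bias[name].append(summ.loc[name, "mode"] - tv)
    table = pd.DataFrame(
        {
            "truth": pd.Series(truth_vals),
            "coverage": pd.Series({k: np.mean(v) for k, v in covered.items()}),
            "mean_bias": pd.Series({k: np.mean(v) for k, v in bias.items()}),
        }
    )
    return table, n_flagged
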