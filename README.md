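# polaripm

Integrated population modelling for polar bears (*Ursus maritimus*), built
around the demographic situation of the Chukchi Sea subpopulation: a mobile,
long-lived carnivore sampled from a study area that covers only a small
fraction of its range, so that temporary emigration, unobservable life-history
states and state uncertainty dominate the inference problem.

The package is aimed at quantitative wildlife ecologists. It provides:

* a two-sex, stage-structured **life cycle** with in/out (temporary
  emigration) versions of every live stage and a single absorbing dead state.
  Females move through `F2Y → F3Y → AFNC ⇄ AFC0 → AFC1 → AFC2` driven by
  breeding probabilities `B1` (available females) and `B2` (females that must
  first lose a litter), weaning probability `W`, and litter survival;
  males through `M2Y → M3Y → M4Y → AM`. Movement is Markovian
  (`ψ1^II, ψ1^OO`), with a separate pair (`ψ2^II, ψ2^OO`) for females
  entering `AFC0`, who den away from the study area;
* **litter thinning**: the age-one litter-size distribution `ω_L1` derived
  from the age-zero distribution `ω_L0` and cub survival `φ_C0`, conditional
  on at least one cub surviving (`φ_L0`), with expected litter sizes
  `l_L0`, `l_L1` as derived parameters;
* an **integrated model** (`IPMModel` / `IPMResults`) combining four data
  types in one posterior: state-specific capture counts
  `n_{s,t} ~ Binomial(p·I_s, N_{s,t})` in spirit (fitted as Poisson around
  the expected trajectory), multinomial age-one litter-size counts,
  binomial weaned/dependent two-year-old counts
  `n_{weanC2,t} ~ Binomial(W, n_{C2,t})`, and a **multievent**
  capture-recapture/telemetry likelihood
  `z_{i,t} | z_{i,t-1} ~ Cat(Θ)`, `y_{i,t} | z_{i,t} ~ Cat(Π)` with hidden
  states marginalised by the forward algorithm;
* moment-matched informative **Beta priors** on subadult/adult survival and
  an informative `Beta(2.1, 11.4)` prior on `B2`, with a vague-only switch;
* **density extrapolation**: closure-corrected density
  `D̄ = N̄_study · q̂ / A_sampling` and habitat-weighted abundance
  `N̄*_CS = (D̄*·A) · Σ_CS h_x / Σ_sampling h_x`, with AFC0 mothers and their
  age-zero cubs added back from the stationary reproductive chain and
  bootstrap uncertainty;
* a separate Poisson-offset **trend model** for age-one cubs per adult
  female (constant vs linear);
* a first-class **synthetic-data generator** producing truth plus all four
  observation datasets, so the whole pipeline runs with no external data.

## Worked example

```python
from polaripm.simulate import SimulationScenario, simulate_bundle
from polaripm.model import IPMModel

bundle = simulate_bundle(SimulationScenario.default(seed=3))
model = IPMModel(bundle.counts, bundle.captures)
res = model.fit(draws=1500, tune=500, walkers=40, seed=1)
print(res.summary().round(3))
```

prints a vital-rates table (posterior mode, 2.5% and 97.5% quantiles,
split-R̂), e.g.:

```
                mode     q2.5    q97.5   rhat
parameter
phi_C0         0.725    0.453    0.951  1.065
phi_AF         0.905    0.869    0.938  1.083
psi1_II        0.755    0.407    0.901  1.098
psi2_OO        0.994    0.873    0.999  1.116
B1             0.853    0.700    0.941  1.075
W              0.229    0.130    0.395  1.068
l_L1           1.568    1.289    1.931    NaN
p              0.086    0.049    0.181  1.126
N_bar_study  170.664  109.174  412.960    NaN
```

Here the dataset was generated at `φ_AF = 0.90`, `B1 = 0.83`, `W = 0.34`,
`p = 0.13` with a true multiyear study-area abundance of 185: every
generating value sits inside its 95% interval. (This run used 2,000 ensemble
steps; R̂ ≈ 1.1 indicates it should be run longer for publication-grade
output — the flag on `res.converged` says so explicitly.)

`res.annual_abundance()` gives the year-by-year `N_study,t` table, and
`polaripm.extrapolation.DensityExtrapolation(res, use_areas, grid).run()`
turns it into densities and a boundary-referenced abundance.

A command-line workflow wraps the same steps:

```bash
polaripm simulate --config config.yaml --seed 7 --out bundle/
polaripm fit --config config.yaml --out fit/          # Table-style summary
polaripm extrapolate --config config.yaml --out ex/   # densities, N_CS
polaripm trend --config config.yaml --out tr/         # cubs per female
```

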