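# Methods

## The demographic model

The life cycle is a pair of stage-structured, year-step projection models.
Stages are crossed with location (inside/outside the study area) to model
temporary emigration, plus one absorbing dead state per sex: 13 female and 9
male states. Each transition-matrix cell is the product
*survival × stage transition × movement*, in that order, so movement
probabilities are conditional on survival; the unallocated mass of each
column goes to the dead state and every column sums to one exactly.

Stage transitions for adult females follow the three-year reproductive
cycle: an available female (`AFNC` or `AFC2`) breeds with probability `B1`
and, if successful, enters `AFC0`; a female with cubs can only re-breed
(probability `B2`) after losing her whole litter; `AFC1` mothers whose
litter survives either keep it (`AFC2`) or wean it before spring sampling
(probability `W`, returning to `AFNC`). Bears entering `AFC0` use their own
movement pair `ψ2` because parturient females den away from the study area.
Three-year-old females transition to `AFNC` only (first possible age-zero
litter at age five); dependent two-year-olds are counted in the independent
subadult states `F2Y`/`M2Y` so that study-area abundance adds only age-zero
and age-one cubs and never double counts.

Litter demography is collapsed to the litter level. Given the age-zero
litter-size simplex `ω_L0` over sizes 1–3 and per-cub survival `φ_C0`,
binomial thinning conditional on at least one survivor gives the litter
survival probability `φ_L0`, the age-one simplex `ω_L1` and expected litter
sizes `l_L0`, `l_L1`; `φ_L1` follows analogously from `φ_C1`. In stochastic
projection, recruitment is coupled to the mother's drawn transition: only
mothers whose outcome implies litter survival (arrival in `AFC2`, or in
`AFNC` via weaning) produce recruits, with the survivor count drawn from
`Binomial(j, φ_C1)` truncated to ≥ 1, `j ~ ω_L1`, split equally at random
between the sexes and placed at the mother's realised destination. The
expected recruitment per `AFC1` mother is then `φ_AF · l_L1 · φ_C1`, and
the long-run stochastic growth rate matches the dominant eigenvalue of the
expectation matrix with recruitment appended (tested).

## Observation models

Four data types share the demographic process:

1. **State counts.** Captures per state and year. The likelihood in the
   joint fit is `n_{s,t} ~ Poisson(p · I_s · N_{s,t})` around the expected
   abundance trajectory (below); the exact binomial form is available as
   `likelihoods.state_count_loglik` and is used generatively. Capture
   probability is fixed to zero in non-sampling years, encoded data-side by
   a sampling indicator.
2. **Age-one litter sizes.** Multinomial in `ω_L1`.
3. **Weaning.** Independent two-year-olds among all observed two-year-olds,
   binomial in `W`.
4. **Multievent histories.** Conditional on first capture, the latent state
   evolves by the transition matrices (recruitment excluded) and each year
   emits an event: physical capture (state certain, inside only, probability
   `p`), or — for females with a functional collar — a telemetry event that
   locates the bear and ascertains its reproductive state with probability
   `δ`, otherwise only the location (`TI?`/`TO?`). Uncollared bears outside
   the study area are unobservable; the dead state emits nothing. A single
   `δ` is used for all states — the minimal identifiable structure — and
   capture supersedes telemetry within a year. Collar status is a known
   covariate built from deployment and failure records, not a modelled
   process. The discrete state path is marginalised by a scaled forward
   algorithm, batched across individuals; it is tested against exhaustive
   path enumeration.

## Latent abundance

Rather than sampling coupled discrete abundances for every state and year,
the fitted model uses a deterministic expected trajectory: one latent total
`N0` (Uniform(0, N_max) prior, default N_max = 5,000) is spread over the
stable stage distribution of the two-sex expectation matrix `A` (with
recruitment), and `N_t = A^t N_0`. Study-area abundance is
`N_study,t = Σ_{s[in]} N_{s,t} + l_L0·N_{AFC0[in],t} + l_L1·N_{AFC1[in],t}`,
averaged over sampling years for `N̄_study`. This sacrifices year-to-year
demographic stochasticity in the latent states (annual `N_study,t` varies
only geometrically) in exchange for a tractable, fully continuous posterior;
the Poisson count likelihood absorbs dispersion around the expectation. This
is the main structural simplification of the package and the main caveat
when interpreting annual abundance estimates.

## Priors and sampling

Subadult/adult survival get Beta priors moment-matched
(`α = m·c`, `β = (1−m)·c`, `c = m(1−m)/sd² − 1`) to published means and
standard deviations (0.89/0.05, 0.93/0.02, 0.82/0.10, 0.89/0.05 for
`φ_SF, φ_AF, φ_SM, φ_AM`); `B2` gets Beta(2.1, 11.4); all other
probabilities are Uniform(0,1) and `ω_L0` flat Dirichlet. A `vague_only`
switch replaces every informative prior with a flat one for sensitivity
runs.

The 18-dimensional posterior is sampled with an affine-invariant ensemble
(emcee), using differential-evolution moves (80% `DEMove`, 20%
`DESnookerMove`), which mix markedly better here than stretch moves. By
default the ensemble starts in a small ball around the posterior mode found
by Nelder–Mead restarts (`init="map"`); `init="prior"` disperses walkers
over the prior instead (used for prior-recovery checks). Walkers serve as
chains for split-R̂; a run with any reported parameter at R̂ ≥ 1.05 is
flagged (warning plus `converged=False`), never silently accepted. Defaults
(40 walkers, 500 warmup + 800 kept steps) are sized for interactive use;
R̂ < 1.05 on real analyses typically needs a few thousand kept steps.

Posterior modes are kernel-density peaks on a 512-point grid (Scott's rule);
integer-valued quantities use the most frequent value; intervals are
empirical 2.5/97.5% quantiles. Goodness of fit uses Freeman–Tukey
discrepancies between observed and replicated counts per data type, giving
Bayesian p-values.

## Density extrapolation

`D̄_sampling = N̄_study · q̂ / A_sampling`, with `q̂` the unweighted mean
over collared females of the proportion of spring locations inside the core
polygon (point-in-polygon; a utilisation-distribution overlap would be a
refinement). Extrapolation uses the AFC0-excluded density `D̄*` because
denning females rarely use the study area:
`N̄*_CS = (D̄*·A_sampling) · Σ_CS h_x / Σ_sampling h_x`, invariant to
rescaling of the habitat metric `h_x` (accepted as a plain cell table;
25 × 25 km cells by convention — no geospatial stack is required). AFC0
mothers are added back via the stationary distribution π of the
survival-conditioned reproductive chain over (AFNC, AFC0, AFC1, AFC2):
the adult-female share of the extrapolated total (from the stable stage
structure) implies `N_AFC0 = N_AF · π/(1−π)`, each mother carrying `l_L0`
age-zero cubs. Uncertainty combines posterior draws with a nonparametric
bootstrap over the per-female use-area proportions; a bootstrap standard
error of the mean abundance (decreasing in the number of draws) is provided
as a Monte-Carlo diagnostic.

## Trend model

Cubs-per-female: `n_C1,t ~ Poisson(rate_t · n_AF,t)` with
`log rate_t = a (+ b·(year − midpoint))`; vague Normal(0,10) priors; the
year covariate is centred at the midpoint. Model comparison reports the
slope interval and DIC. Under a flat prior the constant model's rate has a
closed-form Gamma posterior, used as a conjugacy cross-check in tests.

## Synthetic data

The generator simulates every individual through the life cycle
(equivalent to the multinomial projection, disaggregated), then applies the
observation model: Bernoulli(`p`) captures of inside bears in sampling
years; captured adult females collared with probability 0.9; collars fail
geometrically at 0.2/year; telemetry events emitted per the emission model;
litter sizes drawn from `ω_L1` at capture of `AFC1` mothers; captured
two-year-olds weaned with probability `W`. Histories exist only for bears
actually captured, mirroring conditioning on first capture. The default
scenario uses the point-estimate vital rates, ~300 bears per sex started at
the stable stage distribution, a 9-year span (2008–2016) with two skipped
years (2012, 2014), and `p = 0.13`, yielding roughly 20–30 captures per
sampling year — the scale of the motivating study. `δ` defaults to 0.8, a
representative assignment rate for collar telemetry.

What the generator does **not** emulate: spatially explicit movement,
environmental covariates or temporal variation in rates, individual
heterogeneity in capture or movement probability, collar-induced behaviour
change, and permanent emigration distinct from death. Passing recovery
tests therefore demonstrate internal consistency of the estimator under the
model's own assumptions, not robustness to the heterogeneities expected in
real field data.

## Numerical and testing choices

* Transition columns sum to 1 to 1e-12 over 1,000 random parameter draws.
* The forward algorithm is scaled per step; zero forward mass returns −inf
  (readers reject structurally impossible events, e.g. capture in a
  non-sampling year, with row-level messages).
* `φ_C0 = 0` makes the conditional litter distribution undefined and raises
  a dedicated degenerate-litter error; infeasible Beta moments
  (`sd² ≥ m(1−m)`) raise their own error.
* A reducible reproductive chain with multiple stationary distributions
  raises; chains with a single absorbing class (e.g. `B1 = 0`) are fine.
* Test problem sizes: recovery uses 3 simulate–fit replicates at ~300 bears
  per sex with 1,300-step ensembles, pooling interval coverage across 15
  identifiable parameters (threshold 0.80 against the nominal 0.95, wide
  enough for short-chain Monte-Carlo error); prior recovery checks the
  data-free posterior of `φ_AF` against its Beta prior to within
  Monte-Carlo error. Larger experiments are available through
  `simulate.recovery_experiment`.
* `B2` is weakly identifiable by design of the data; tests assert it stays
  near its informative prior rather than requiring calibrated coverage.
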