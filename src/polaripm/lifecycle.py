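"""Sex-specific polar bear life cycles with temporary emigration.

The demographic core is a pair of stage-structured projection models, one per
sex, in which every live stage exists in an "inside" and an "outside" version
relative to the sampled study area, plus a single absorbing dead state.
Movement between the two locations is Markovian: the probability of being
inside next year depends on where the bear is this year, and females that
produce a new litter of age-zero cubs (entering state ``AFC0``) use their own
movement pair because parturient females den away from the study area.

Stages
------
Males: subadults ``M2Y``, ``M3Y``, ``M4Y`` (ages 2-4) and adults ``AM``.
Females: subadults ``F2Y``, ``F3Y`` (ages 2-3) and adult reproductive states
``AFNC`` (no cubs), ``AFC0`` (age-zero cubs), ``AFC1`` (age-one cubs) and
``AFC2`` (age-two cubs).

Cub demography is carried by the mother's state.  A litter's fate is
summarised by litter-survival probabilities (``phi_L0``, ``phi_L1`` = the
probability at least one cub survives the year) and by the litter-size
distributions before (``omega_L0``) and after (``omega_L1``) first-year
thinning; see :func:`litter_thinning`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .exceptions import DegenerateLitterError, InvalidInputError

__all__ = [
    "StateSpace",
    "VitalRates",
    "LitterModel",
    "TransitionMatrix",
    "FEMALE",
    "MALE",
    "litter_thinning",
    "build_transition_matrix",
    "project_population",
    "joint_expectation_matrix",
    "stable_stage_distribution",
]

FEMALE = "female"
MALE = "male"

_FEMALE_CLASSES = ("F2Y", "F3Y", "AFNC", "AFC0", "AFC1", "AFC2")
_MALE_CLASSES = ("M2Y", "M3Y", "M4Y", "AM")
_ADULT_FEMALE_CLASSES = ("AFNC", "AFC0", "AFC1", "AFC2")


@dataclass(frozen=True)
class StateSpace:
    """Ordered state list for one sex: each live stage in/out, then dead."""

    sex: str
    classes: tuple[str, ...]
    states: tuple[str, ...]

    @classmethod
    def for_sex(cls, sex: str) -> "StateSpace":
        if sex == FEMALE:
            stage_classes = _FEMALE_CLASSES
        elif sex == MALE:
            stage_classes = _MALE_CLASSES
        else:
            raise InvalidInputError(f"unknown sex label: {sex!r}")
        states = tuple(
            f"{c}_{loc}" for c in stage_classes for loc in ("in", "out")
        ) + ("dead",)
        return cls(sex=sex, classes=stage_classes, states=states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def dead_index(self) -> int:
        return self.n_states - 1

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise InvalidInputError(
                f"unknown state {state!r} for sex {self.sex!r}"
            ) from None

    def class_of(self, idx: int) -> str:
        if idx == self.dead_index:
            return "dead"
        return self.classes[idx // 2]

    def location_of(self, idx: int) -> str:
        if idx == self.dead_index:
            return "dead"
        return "in" if idx % 2 == 0 else "out"

    def is_inside(self, idx: int) -> bool:
        return idx != self.dead_index and idx % 2 == 0

    @property
    def inside_indicator(self) -> np.ndarray:
        """I_s: 1 for inside live states, 0 for outside and dead."""
        ind = np.zeros(self.n_states)
        ind[: self.dead_index : 2] = 1.0
        return ind

    @property
    def live_indices(self) -> np.ndarray:
        return np.arange(self.dead_index)


FEMALE_STATES = StateSpace.for_sex(FEMALE)
MALE_STATES = StateSpace.for_sex(MALE)


def _check_prob(name: str, value: float, closed: bool = True) -> None:
    lo_ok = value >= 0.0 if closed else value > 0.0
    if not (lo_ok and value <= 1.0):
        raise InvalidInputError(f"{name}={value} is not a valid probability")


@dataclass(frozen=True)
class VitalRates:
    """Demographic, movement and detection parameters of the life cycle.

    Survival: ``phi_C0``/``phi_C1`` cubs, ``phi_SF``/``phi_SM`` subadults,
    ``phi_AF``/``phi_AM`` adults.  Movement: ``psi1_II``/``psi1_OO`` stay-in /
    stay-out for everyone except females entering AFC0, which use
    ``psi2_II``/``psi2_OO``.  Breeding: ``B1`` for available females
    (AFNC/AFC2), ``B2`` for females that must lose a current litter first.
    ``W`` is the probability a two-year-old weans before spring sampling.
    ``omega_L0`` is the age-zero litter-size simplex over sizes 1-3.
    ``p`` is capture probability, ``delta`` the probability telemetry
    ascertains a collared female's reproductive state.
    """

    phi_C0: float
    phi_C1: float
    phi_SF: float
    phi_AF: float
    phi_SM: float
    phi_AM: float
    psi1_II: float
    psi1_OO: float
    psi2_II: float
    psi2_OO: float
    B1: float
    B2: float
    W: float
    omega_L0: tuple[float, float, float]
    p: float
    delta: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "omega_L0":
                continue
            _check_prob(f.name, getattr(self, f.name))
        w = np.asarray(self.omega_L0, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise InvalidInputError(f"omega_L0={self.omega_L0} is not a 3-simplex")
        object.__setattr__(self, "omega_L0", tuple(float(x) for x in w))

    @classmethod
    def chukchi_modes(cls, p: float = 0.13, delta: float = 0.8) -> "VitalRates":
        """Posterior-mode point estimates for the Chukchi Sea subpopulation.

        ``omega_L0`` is set to (0.10, 0.62, 0.28), which has expected litter
        size 2.18, matching the estimated mean age-zero litter size.  ``p``
        and ``delta`` defaults are representative detection/assignment values.
        """
        return cls(
            phi_C0=0.62, phi_C1=0.92, phi_SF=0.79, phi_AF=0.90,
            phi_SM=0.71, phi_AM=0.89,
            psi1_II=0.59, psi1_OO=0.78, psi2_II=0.01, psi2_OO=0.98,
            B1=0.83, B2=0.10, W=0.34,
            omega_L0=(0.10, 0.62, 0.28), p=p, delta=delta,
        )

    def survival_for(self, sex: str, stage: str) -> float:
        if sex == MALE:
            return self.phi_AM if stage == "AM" else self.phi_SM
        return self.phi_AF if stage in _ADULT_FEMALE_CLASSES else self.phi_SF

    def replace(self, **kw) -> "VitalRates":
        return replace(self, **kw)


@dataclass(frozen=True)
class LitterModel:
    """Derived litter quantities linking C0 and C1 litters.

    ``phi_L0``/``phi_L1``: probability at least one cub in an age-0/age-1
    litter survives the year.  ``omega_L1``: age-one litter-size simplex,
    obtained by binomial thinning of ``omega_L0`` conditional on at least one
    survivor.  ``l_L0``/``l_L1``: expected litter sizes.
    """

    phi_L0: float
    phi_L1: float
    omega_L1: tuple[float, float, float]
    l_L0: float
    l_L1: float

    def __post_init__(self) -> None:
        w = np.asarray(self.omega_L1, dtype=float)
        if abs(w.sum() - 1.0) > 1e-8 or np.any(w < -1e-12):
            raise InvalidInputError(f"omega_L1={self.omega_L1} is not a simplex")
        if not (1.0 - 1e-9 <= self.l_L0 <= 3.0 + 1e-9):
            raise InvalidInputError(f"l_L0={self.l_L0} outside [1, 3]")
        if not (1.0 - 1e-9 <= self.l_L1 <= 3.0 + 1e-9):
            raise InvalidInputError(f"l_L1={self.l_L1} outside [1, 3]")


def litter_thinning(
    omega_L0, phi_C0: float, phi_C1: float
) -> LitterModel:
    """Thin the age-zero litter-size distribution by first-year cub survival.

    Each cub in a litter of size k survives independently with probability
    ``phi_C0``; the age-one litter-size distribution is the distribution of
    the survivor count conditional on at least one survivor:

        phi_L0     = sum_k omega_L0[k] (1 - (1-phi_C0)^k)
        omega_L1[j] = sum_k omega_L0[k] Binom(j; k, phi_C0) / phi_L0
        phi_L1     = sum_j omega_L1[j] (1 - (1-phi_C1)^j)

    with expected litter sizes l_L0 and l_L1 as means of the two simplices.
    """
    w0 = np.asarray(omega_L0, dtype=float)
    if w0.shape != (3,) or np.any(w0 < 0) or abs(w0.sum() - 1.0) > 1e-8:
        raise InvalidInputError(f"omega_L0={omega_L0} is not a 3-simplex")
    for name, v in (("phi_C0", phi_C0), ("phi_C1", phi_C1)):
        _check_prob(name, v)
    if phi_C0 == 0.0:
        raise DegenerateLitterError(
            "phi_C0=0 gives phi_L0=0; the conditional C1 litter distribution "
            "is undefined"
        )
    sizes = np.arange(1, 4)
    phi_L0 = float(np.sum(w0 * (1.0 - (1.0 - phi_C0) ** sizes)))
    w1 = np.zeros(3)
    for j in range(1, 4):
        w1[j - 1] = sum(
            w0[k - 1]
            * math.comb(k, j)
            * phi_C0**j
            * (1.0 - phi_C0) ** (k - j)
            for k in range(j, 4)
        )
    w1 /= phi_L0
    phi_L1 = float(np.sum(w1 * (1.0 - (1.0 - phi_C1) ** sizes)))
    return LitterModel(
        phi_L0=phi_L0,
        phi_L1=phi_L1,
        omega_L1=tuple(w1),
        l_L0=float(np.sum(sizes * w0)),
        l_L1=float(np.sum(sizes * w1)),
    )


@dataclass(frozen=True)
class TransitionMatrix:
    """One-step transition probabilities Theta[destination, source], one sex.

    Columns sum to one; the residual after survival goes to the absorbing
    dead state.
    """

    space: StateSpace
    theta: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        n = self.space.n_states
        if th.shape != (n, n):
            raise InvalidInputError(f"theta shape {th.shape} != ({n}, {n})")
        object.__setattr__(self, "theta", th)

    def prob(self, source: str, dest: str) -> float:
        return float(self.theta[self.space.index(dest), self.space.index(source)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.theta, index=self.space.states, columns=self.space.states
        )

    def to_text(self, path) -> None:
        """Plain rectangular text export with state labels as headers."""
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def _class_transitions(
    sex: str, rates: VitalRates, litter: LitterModel
) -> dict[str, list[tuple[str, float]]]:
    """Stage-to-stage probabilities conditional on survival, per source class."""
    if sex == MALE:
        return {
            "M2Y": [("M3Y", 1.0)],
            "M3Y": [("M4Y", 1.0)],
            "M4Y": [("AM", 1.0)],
            "AM": [("AM", 1.0)],
        }
    B1, B2, W = rates.B1, rates.B2, rates.W
    pL0, pL1 = litter.phi_L0, litter.phi_L1
    return {
        "F2Y": [("F3Y", 1.0)],
        "F3Y": [("AFNC", 1.0)],
        "AFNC": [("AFC0", B1), ("AFNC", 1.0 - B1)],
        "AFC0": [
            ("AFC1", pL0),
            ("AFC0", (1.0 - pL0) * B2),
            ("AFNC", (1.0 - pL0) * (1.0 - B2)),
        ],
        "AFC1": [
            ("AFC2", pL1 * (1.0 - W)),
            ("AFNC", pL1 * W + (1.0 - pL1) * (1.0 - B2)),
            ("AFC0", (1.0 - pL1) * B2),
        ],
        "AFC2": [("AFC0", B1), ("AFNC", 1.0 - B1)],
    }


def _movement_split(rates: VitalRates, dest_class: str, src_loc: str):
    """(P(dest in), P(dest out)) given the source location.

    Destinations entering AFC0 use the parturient movement pair psi2.
    """
    if dest_class == "AFC0":
        psi_II, psi_OO = rates.psi2_II, rates.psi2_OO
    else:
        psi_II, psi_OO = rates.psi1_II, rates.psi1_OO
    if src_loc == "in":
        return psi_II, 1.0 - psi_II
    return 1.0 - psi_OO, psi_OO


def build_transition_matrix(
    sex: str, rates: VitalRates, litter: LitterModel | None = None
) -> TransitionMatrix:
    """Assemble Theta for one sex: survive, then transition stage, then move.

    Each live cell is the product survival x stage-transition x movement;
    movement is conditional on survival, and the unallocated mass (mortality)
    goes to the single absorbing dead state.
    """
    space = StateSpace.for_sex(sex)
    if litter is None:
        litter = litter_thinning(rates.omega_L0, rates.phi_C0, rates.phi_C1)
    ct = _class_transitions(sex, rates, litter)
    n = space.n_states
    theta = np.zeros((n, n))
    for j in range(space.dead_index):
        src_class = space.class_of(j)
        src_loc = space.location_of(j)
        surv = rates.survival_for(sex, src_class)
        for dest_class, prob in ct[src_class]:
            pin, pout = _movement_split(rates, dest_class, src_loc)
            theta[space.index(f"{dest_class}_in"), j] += surv * prob * pin
            theta[space.index(f"{dest_class}_out"), j] += surv * prob * pout
        theta[space.dead_index, j] = 1.0 - theta[: space.dead_index, j].sum()
    theta[space.dead_index, space.dead_index] = 1.0
    return TransitionMatrix(space=space, theta=theta)


def _wean_share_given_afnc(litter: LitterModel, rates: VitalRates) -> float:
    """P(litter survived | AFC1 mother arrived in AFNC)."""
    pL1, W, B2 = litter.phi_L1, rates.W, rates.B2
    denom = pL1 * W + (1.0 - pL1) * (1.0 - B2)
    if denom == 0.0:
        return 0.0
    return pL1 * W / denom


def _positive_binomial_rvs(n_trials, p, rng):
    """Binomial(n, p) conditioned on >= 1 success, elementwise."""
    out = np.empty(len(n_trials), dtype=int)
    for i, n in enumerate(n_trials):
        while True:
            x = rng.binomial(n, p)
            if x > 0:
                out[i] = x
                break
    return out


def project_population(
    counts_female,
    counts_male,
    theta_female: TransitionMatrix,
    theta_male: TransitionMatrix,
    litter: LitterModel,
    rates: VitalRates,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """One stochastic projection step for both sexes.

    Occupants of each state are allocated to destinations by a multinomial
    draw over the state's transition column.  Mothers in AFC1 whose drawn
    transition implies litter survival (arrival in AFC2, or in AFNC via
    weaning) recruit: litter size j ~ omega_L1, survivors ~ Binomial(j,
    phi_C1) conditional on at least one, split equally at random between
    F2Y and M2Y at the mother's realised in/out destination.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    nf = np.asarray(counts_female, dtype=float)
    nm = np.asarray(counts_male, dtype=float)
    for arr, space in ((nf, FEMALE_STATES), (nm, MALE_STATES)):
        if arr.shape != (space.n_states,) or np.any(arr < 0):
            raise InvalidInputError("state counts must be nonnegative, full-length")
        if not np.allclose(arr, np.round(arr)):
            raise InvalidInputError("state counts must be integers")
    nf = nf.astype(int)
    nm = nm.astype(int)

    next_m = np.zeros(MALE_STATES.n_states, dtype=int)
    for j in range(MALE_STATES.n_states):
        if nm[j]:
            next_m += rng.multinomial(nm[j], theta_male.theta[:, j])

    next_f = np.zeros(FEMALE_STATES.n_states, dtype=int)
    space = FEMALE_STATES
    recruits_by_loc = {"in": 0, "out": 0}
    afc1_idx = {space.index("AFC1_in"), space.index("AFC1_out")}
    afc2_in, afc2_out = space.index("AFC2_in"), space.index("AFC2_out")
    afnc_in, afnc_out = space.index("AFNC_in"), space.index("AFNC_out")
    wean_share = _wean_share_given_afnc(litter, rates)
    for j in range(space.n_states):
        if not nf[j]:
            continue
        dest = rng.multinomial(nf[j], theta_female.theta[:, j])
        next_f += dest
        if j in afc1_idx:
            # mothers whose transition implies the C1 litter survived recruit
            n_surviving_litters = {
                "in": dest[afc2_in] + rng.binomial(dest[afnc_in], wean_share),
                "out": dest[afc2_out] + rng.binomial(dest[afnc_out], wean_share),
            }
            for loc, k in n_surviving_litters.items():
                if k:
                    sizes = rng.choice(
                        [1, 2, 3], size=k, p=np.asarray(litter.omega_L1)
                    )
                    recruits_by_loc[loc] += int(
                        _positive_binomial_rvs(sizes, rates.phi_C1, rng).sum()
                    )
    for loc, n_rec in recruits_by_loc.items():
        if n_rec:
            n_female = rng.binomial(n_rec, 0.5)
            next_f[space.index(f"F2Y_{loc}")] += n_female
            next_m[MALE_STATES.index(f"M2Y_{loc}")] += n_rec - n_female
    return next_f, next_m


def joint_expectation_matrix(
    rates: VitalRates,
    litter: LitterModel | None = None,
    theta_female: TransitionMatrix | None = None,
    theta_male: TransitionMatrix | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Expectation projection matrix over live states of both sexes.

    Block-diagonal in the two sex transition matrices (live states only) plus
    recruitment rows: each AFC1 mother contributes an expected
    ``0.5 * phi_AF * l_L1 * phi_C1`` recruits to each of F2Y and M2Y, placed
    at the mother's expected destination location (psi1 movement pair).
    """
    if litter is None:
        litter = litter_thinning(rates.omega_L0, rates.phi_C0, rates.phi_C1)
    tf = theta_female if theta_female is not None else build_transition_matrix(
        FEMALE, rates, litter
    )
    tm = theta_male if theta_male is not None else build_transition_matrix(
        MALE, rates, litter
    )
    nf, nm = FEMALE_STATES.dead_index, MALE_STATES.dead_index
    labels = [f"F:{s}" for s in FEMALE_STATES.states[:nf]] + [
        f"M:{s}" for s in MALE_STATES.states[:nm]
    ]
    A = np.zeros((nf + nm, nf + nm))
    A[:nf, :nf] = tf.theta[:nf, :nf]
    A[nf:, nf:] = tm.theta[:nm, :nm]
    per_mother = rates.phi_AF * litter.l_L1 * rates.phi_C1
    for loc in ("in", "out"):
        j = FEMALE_STATES.index(f"AFC1_{loc}")
        pin, pout = _movement_split(rates, "F2Y", loc)
        for dest_loc, pmove in (("in", pin), ("out", pout)):
            A[FEMALE_STATES.index(f"F2Y_{dest_loc}"), j] += 0.5 * per_mother * pmove
            A[nf + MALE_STATES.index(f"M2Y_{dest_loc}"), j] += (
                0.5 * per_mother * pmove
            )
    return A, labels


def stable_stage_distribution(A: np.ndarray) -> tuple[float, np.ndarray]:
    """Dominant eigenvalue and normalised nonnegative right eigenvector."""
    vals, vecs = np.linalg.eig(A)
    k = int(np.argmax(vals.real))
    lam = float(vals[k].real)
    v = np.abs(vecs[:, k].real)
    return lam, v / v.sum()
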