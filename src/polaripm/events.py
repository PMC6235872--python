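"""Multievent observation process: event alphabet, emissions, forward algorithm.

Observed events map probabilistically to latent life-cycle states.  Physical
capture identifies the full state of a bear inside the study area; telemetry
from a functional collar locates a female (inside or outside) and ascertains
her reproductive state with probability ``delta``.  Males, and females
without an active collar, can only be detected by capture, so bears outside
the study area are then unobservable.

Event codes (delimited-text representation):

``0``            not observed
``C:<class>``    physical capture, assigned to the inside state of <class>
``T:<state>``    telemetry alive at <state> (in or out), reproductive state
                 ascertained
``TI?``/``TO?``  telemetry alive inside/outside, reproductive state unknown

Capture histories are analysed conditional on first capture; the likelihood
marginalises the hidden state path with the forward algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ImpossibleDataError, InvalidInputError
from .lifecycle import FEMALE, MALE, StateSpace, TransitionMatrix

__all__ = [
    "event_alphabet",
    "build_emission_row",
    "emission_prob_given_states",
    "parse_event",
    "MultieventLikelihood",
    "forward_loglik",
    "multievent_loglik",
]

NOT_OBSERVED = "0"
TELEM_UNK_IN = "TI?"
TELEM_UNK_OUT = "TO?"

# emission "type codes" used by the vectorised likelihood; the per-evaluation
# value of each code is a simple function of (p_t, delta)
_E_ZERO, _E_ONE, _E_P, _E_1MP, _E_1MP_D, _E_1MP_1MD, _E_D, _E_1MD = range(8)


def _emission_values(p: float, delta: float) -> np.ndarray:
    return np.array(
        [0.0, 1.0, p, 1.0 - p, (1.0 - p) * delta, (1.0 - p) * (1.0 - delta),
         delta, 1.0 - delta]
    )


def event_alphabet(space: StateSpace) -> list[str]:
    """All event codes defined for one sex's state space."""
    codes = [NOT_OBSERVED]
    codes += [f"C:{c}" for c in space.classes]
    codes += [f"T:{s}" for s in space.states[: space.dead_index]]
    codes += [TELEM_UNK_IN, TELEM_UNK_OUT]
    return codes


def parse_event(code: str, space: StateSpace) -> str:
    """Validate an event code against a state space; returns the code."""
    if code in (NOT_OBSERVED, TELEM_UNK_IN, TELEM_UNK_OUT):
        return code
    if code.startswith("C:"):
        if code[2:] not in space.classes:
            raise InvalidInputError(f"capture event {code!r}: unknown class")
        return code
    if code.startswith("T:"):
        state = code[2:]
        if state not in space.states[: space.dead_index]:
            raise InvalidInputError(f"telemetry event {code!r}: unknown state")
        return code
    raise InvalidInputError(f"unrecognised event code {code!r}")


def _emission_type_row(
    space: StateSpace, state_idx: int, sex: str, collar_active: int
) -> dict[str, int]:
    """Map event code -> emission type code for one latent state."""
    row: dict[str, int] = {}
    if state_idx == space.dead_index:
        row[NOT_OBSERVED] = _E_ONE
        return row
    cls = space.class_of(state_idx)
    inside = space.is_inside(state_idx)
    telemetry = sex == FEMALE and collar_active
    if inside:
        row[f"C:{cls}"] = _E_P
        if telemetry:
            row[f"T:{space.states[state_idx]}"] = _E_1MP_D
            row[TELEM_UNK_IN] = _E_1MP_1MD
        else:
            row[NOT_OBSERVED] = _E_1MP
    else:
        if telemetry:
            row[f"T:{space.states[state_idx]}"] = _E_D
            row[TELEM_UNK_OUT] = _E_1MD
        else:
            row[NOT_OBSERVED] = _E_ONE
    return row


def build_emission_row(
    space: StateSpace,
    state: str | int,
    sex: str,
    collar_active: int,
    p: float,
    delta: float,
) -> dict[str, float]:
    """Detection-probability vector over the event alphabet for one state.

    Rows sum to one.  Capture supersedes telemetry within a year: a collared
    female inside the study area is captured with probability ``p`` and
    otherwise yields a telemetry event.
    """
    idx = space.index(state) if isinstance(state, str) else int(state)
    types = _emission_type_row(space, idx, sex, collar_active)
    vals = _emission_values(p, delta)
    row = {code: 0.0 for code in event_alphabet(space)}
    for code, t in types.items():
        row[code] = float(vals[t])
    return row


def emission_prob_given_states(
    space: StateSpace,
    event: str,
    sex: str,
    collar_active: int,
    p: float,
    delta: float,
) -> np.ndarray:
    """P(event | state) for every state — one forward-algorithm update vector."""
    event = parse_event(event, space)
    out = np.zeros(space.n_states)
    for idx in range(space.n_states):
        row_types = _emission_type_row(space, idx, sex, collar_active)
        if event in row_types:
            out[idx] = _emission_values(p, delta)[row_types[event]]
    return out


@dataclass
class _SexBatch:
    first_year: np.ndarray           # (n_ind,) year index of first capture
    init_state: np.ndarray           # (n_ind,) latent state index at first capture
    type_codes: np.ndarray           # (n_ind, n_years, n_states) int8


class MultieventLikelihood:
    """Precompiled forward-algorithm likelihood for a set of capture histories.

    Precomputes, per individual-year, the emission *type* of the observed
    event under every latent state; evaluation then only gathers the type
    values for the current (p, delta) and runs a batched scaled forward pass.
    """

    def __init__(self, captures, n_years: int, sampling_mask: np.ndarray):
        """``captures``: CaptureData; year indices must lie in [0, n_years)."""
        self.n_years = n_years
        self.sampling_mask = np.asarray(sampling_mask, dtype=bool)
        self.batches: dict[str, _SexBatch] = {}
        self.spaces = {FEMALE: StateSpace.for_sex(FEMALE), MALE: StateSpace.for_sex(MALE)}
        for sex in (FEMALE, MALE):
            batch = self._build_batch(captures, sex)
            if batch is not None:
                self.batches[sex] = batch

    def _build_batch(self, captures, sex: str):
        space = self.spaces[sex]
        rows = captures.table[captures.table["sex"] == sex]
        if len(rows) == 0:
            return None
        ids = list(dict.fromkeys(rows["id"]))
        n_ind = len(ids)
        first_year = np.zeros(n_ind, dtype=int)
        init_state = np.zeros(n_ind, dtype=int)
        types = np.zeros((n_ind, self.n_years, space.n_states), dtype=np.int8)
        for i, ind in enumerate(ids):
            hist = rows[rows["id"] == ind].sort_values("year")
            years = hist["year"].to_numpy()
            events = hist["event_code"].to_numpy()
            collars = hist["collar_active"].to_numpy()
            first = int(years[0])
            if not events[0].startswith("C:"):
                raise ImpossibleDataError(
                    f"individual {ind!r}: first event {events[0]!r} is not a "
                    "physical capture"
                )
            first_year[i] = first
            init_state[i] = space.index(f"{events[0][2:]}_in")
            for yr, ev, col in zip(years[1:], events[1:], collars[1:]):
                t = int(yr)
                ev = parse_event(ev, space)
                if ev.startswith("C:") and not self.sampling_mask[t]:
                    raise ImpossibleDataError(
                        f"individual {ind!r}: capture event in non-sampling "
                        f"year index {t}"
                    )
                for s in range(space.n_states):
                    row_types = _emission_type_row(space, s, sex, int(col))
                    types[i, t, s] = row_types.get(ev, _E_ZERO)
        return _SexBatch(first_year=first_year, init_state=init_state, type_codes=types)

    def __call__(
        self,
        theta_female: TransitionMatrix,
        theta_male: TransitionMatrix,
        p: float,
        delta: float,
    ) -> float:
        total = 0.0
        thetas = {FEMALE: theta_female.theta, MALE: theta_male.theta}
        for sex, batch in self.batches.items():
            total += self._forward_batch(batch, thetas[sex].T, p, delta)
            if not np.isfinite(total):
                return -np.inf
        return float(total)

    def _forward_batch(self, batch, thetaT, p, delta) -> float:
        n_ind, n_years, n_states = batch.type_codes.shape
        # per-year emission values: capture probability is 0 outside sampling
        vals = np.empty((n_years, 8))
        for t in range(n_years):
            vals[t] = _emission_values(p if self.sampling_mask[t] else 0.0, delta)
        alpha = np.zeros((n_ind, n_states))
        alpha[np.arange(n_ind), batch.init_state] = 1.0
        loglik = np.zeros(n_ind)
        for t in range(1, n_years):
            active = batch.first_year < t
            if not np.any(active):
                continue
            em = vals[t][batch.type_codes[active, t, :]]
            a = (alpha[active] @ thetaT) * em
            c = a.sum(axis=1)
            if np.any(c <= 0.0):
                return -np.inf
            alpha[active] = a / c[:, None]
            loglik[active] += np.log(c)
        return float(loglik.sum())


def forward_loglik(
    events: list[tuple[str, int]],
    first_state: str,
    sex: str,
    theta: TransitionMatrix,
    p_by_year,
    delta: float,
) -> float:
    """Reference (unbatched) forward log-likelihood for one history.

    ``events``: list of (event_code, collar_active) for each year after first
    capture, in order; ``p_by_year`` gives the capture probability for those
    same years.  Conditional on first capture, a length-0 history has
    log-likelihood 0.
    """
    space = theta.space
    alpha = np.zeros(space.n_states)
    alpha[space.index(first_state)] = 1.0
    ll = 0.0
    for (ev, collar), p_t in zip(events, p_by_year):
        em = emission_prob_given_states(space, parse_event(ev, space), sex,
                                        int(collar), p_t, delta)
        alpha = (theta.theta @ alpha) * em
        c = alpha.sum()
        if c <= 0.0:
            return -np.inf
        alpha /= c
        ll += np.log(c)
    return float(ll)


def multievent_loglik(
    captures,
    theta_female: TransitionMatrix,
    theta_male: TransitionMatrix,
    p: float,
    delta: float,
    n_years: int,
    sampling_mask,
) -> float:
    """Total forward-algorithm log-likelihood of a set of capture histories.

    Convenience wrapper over :class:`MultieventLikelihood` for one-off
    evaluations; repeated evaluation (e.g. inside a sampler) should build
    the class once and call it.
    """
    return MultieventLikelihood(captures, n_years, np.asarray(sampling_mask))(
        theta_female, theta_male, p, delta
    )
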