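"""Observation model: emission rows and forward-algorithm likelihood."""

import itertools

import numpy as np
import pandas as pd
import pytest

from polaripm.data import CaptureData
from polaripm.events import (
    MultieventLikelihood,
    build_emission_row,
    emission_prob_given_states,
    event_alphabet,
    forward_loglik,
)
from polaripm.exceptions import ImpossibleDataError, InvalidInputError
from polaripm.lifecycle import (
    FEMALE,
    MALE,
    FEMALE_STATES,
    MALE_STATES,
    build_transition_matrix,
)

from conftest import random_rates


def enumeration_loglik(events, first_state, sex, theta, p_by_year, delta):
    """Oracle: total probability by exhaustive latent-path enumeration."""
    space = theta.space
    total = 0.0
    for path in itertools.product(range(space.n_states), repeat=len(events)):
        prob = 1.0
        prev = space.index(first_state)
        for (ev, collar), s, p_t in zip(events, path, p_by_year):
            prob *= theta.theta[s, prev]
            row = build_emission_row(space, s, sex, collar, p_t, delta)
            prob *= row.get(ev, 0.0)
            prev = s
            if prob == 0.0:
                break
        total += prob
    return np.log(total) if total > 0 else -np.inf


class TestEmissionRows:
    def test_male_inside(self):
        row = build_emission_row(MALE_STATES, "AM_in", MALE, 0, 0.13, 0.8)
        assert row["C:AM"] == pytest.approx(0.13)
        assert row["0"] == pytest.approx(0.87)
        assert sum(v for k, v in row.items() if k not in ("C:AM", "0")) == 0

    def test_outside_uncollared_unobservable(self):
        row = build_emission_row(MALE_STATES, "AM_out", MALE, 0, 0.13, 0.8)
        assert row["0"] == 1.0
        row = build_emission_row(FEMALE_STATES, "AFNC_out", FEMALE, 0, 0.13, 0.8)
        assert row["0"] == 1.0

    def test_dead_emits_nothing(self):
        for space, sex in ((FEMALE_STATES, FEMALE), (MALE_STATES, MALE)):
            for collar in (0, 1):
                row = build_emission_row(space, "dead", sex, collar, 0.5, 0.5)
                assert row["0"] == 1.0

    def test_collared_female_outside(self):
        row = build_emission_row(FEMALE_STATES, "AFC1_out", FEMALE, 1, 0.13, 0.8)
        assert row["T:AFC1_out"] == pytest.approx(0.8)
        assert row["TO?"] == pytest.approx(0.2)

    def test_collared_female_inside_capture_supersedes(self):
        row = build_emission_row(FEMALE_STATES, "AFNC_in", FEMALE, 1, 0.13, 0.8)
        assert row["C:AFNC"] == pytest.approx(0.13)
        assert row["T:AFNC_in"] == pytest.approx(0.87 * 0.8)
        assert row["TI?"] == pytest.approx(0.87 * 0.2)

    def test_rows_sum_to_one_everywhere(self):
        for space, sex in ((FEMALE_STATES, FEMALE), (MALE_STATES, MALE)):
            for idx in range(space.n_states):
                for collar in (0, 1):
                    row = build_emission_row(space, idx, sex, collar, 0.3, 0.7)
                    assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)

    def test_alphabet_covers_emissions(self):
        codes = set(event_alphabet(FEMALE_STATES))
        assert "C:AFC0" in codes and "T:AFC2_out" in codes
        assert {"0", "TI?", "TO?"} <= codes


class TestForwardAlgorithm:
    @pytest.mark.parametrize("sex", [FEMALE, MALE])
    def test_matches_path_enumeration(self, sex):
        rng = np.random.default_rng(31)
        histories = {
            FEMALE: [
                [("0", 0), ("0", 0)],
                [("T:AFC1_out", 1), ("TI?", 1), ("C:AFNC", 0)],
                [("TO?", 1), ("0", 0), ("0", 0), ("C:AFC2", 1)],
            ],
            MALE: [
                [("0", 0)],
                [("0", 0), ("C:AM", 0), ("0", 0)],
                [("0", 0), ("0", 0), ("0", 0), ("C:AM", 0)],
            ],
        }[sex]
        first = {"female": "AFNC_in", "male": "M4Y_in"}[sex]
        for _ in range(5):
            rates = random_rates(rng)
            theta = build_transition_matrix(sex, rates)
            for events in histories:
                p_by_year = [rates.p] * len(events)
                got = forward_loglik(events, first, sex, theta, p_by_year,
                                     rates.delta)
                want = enumeration_loglik(events, first, sex, theta,
                                          p_by_year, rates.delta)
                assert got == pytest.approx(want, rel=1e-10)

    def test_length_one_history_is_fully_conditioned(self, modes):
        theta = build_transition_matrix(FEMALE, modes)
        assert forward_loglik([], "AFNC_in", FEMALE, theta, [], 0.8) == 0.0

    def test_fully_observed_limit(self, modes):
        # with certain detection and assignment the likelihood is the
        # plain Markov-chain product over observed states
        rates = modes.replace(p=1.0, delta=1.0)
        theta = build_transition_matrix(FEMALE, rates)
        events = [("C:AFC0", 1), ("T:AFC1_out", 1)]
        got = forward_loglik(events, "AFNC_in", FEMALE, theta, [1.0, 1.0], 1.0)
        want = np.log(
            theta.prob("AFNC_in", "AFC0_in") * 1.0
        ) + np.log(theta.prob("AFC0_in", "AFC1_out") * 1.0)
        assert got == pytest.approx(want, rel=1e-10)

    def test_batched_matches_reference(self, modes):
        theta_f = build_transition_matrix(FEMALE, modes)
        theta_m = build_transition_matrix(MALE, modes)
        sampling = np.array([True, True, False, True, True])
        rows = []
        specs = [
            ("f1", FEMALE, 0, "C:AFNC",
             [("T:AFC0_out", 1), ("TO?", 1), ("0", 0), ("C:AFNC", 0)]),
            ("f2", FEMALE, 1, "C:AFC1", [("0", 0), ("0", 0), ("0", 0)]),
            ("m1", MALE, 0, "C:M3Y", [("0", 0), ("0", 0), ("C:AM", 0), ("0", 0)]),
        ]
        expected = 0.0
        for ind, sex, first_t, first_ev, events in specs:
            rows.append({"id": ind, "sex": sex, "year": first_t,
                         "event_code": first_ev, "collar_active": 0})
            for k, (ev, col) in enumerate(events):
                rows.append({"id": ind, "sex": sex, "year": first_t + 1 + k,
                             "event_code": ev,
                             "collar_active": col if sex == FEMALE else 0})
            theta = theta_f if sex == FEMALE else theta_m
            p_by_year = [modes.p if sampling[first_t + 1 + k] else 0.0
                         for k in range(len(events))]
            expected += forward_loglik(
                events, f"{first_ev[2:]}_in", sex, theta, p_by_year, modes.delta
            )
        ml = MultieventLikelihood(CaptureData(pd.DataFrame(rows)), 5, sampling)
        got = ml(theta_f, theta_m, modes.p, modes.delta)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_capture_in_non_sampling_year_impossible(self):
        rows = pd.DataFrame([
            {"id": "f1", "sex": FEMALE, "year": 0, "event_code": "C:AFNC",
             "collar_active": 0},
            {"id": "f1", "sex": FEMALE, "year": 1, "event_code": "C:AFNC",
             "collar_active": 0},
        ])
        with pytest.raises(ImpossibleDataError):
            MultieventLikelihood(CaptureData(rows), 2,
                                 np.array([True, False]))

    def test_unknown_event_code_rejected(self):
        with pytest.raises(InvalidInputError):
            emission_prob_given_states(FEMALE_STATES, "X:?", FEMALE, 0, 0.1, 0.5)
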