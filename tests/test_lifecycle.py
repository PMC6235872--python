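"""Life-cycle machinery: litter thinning, transition matrices, projection."""

import math

import numpy as np
import pytest

from polaripm.exceptions import DegenerateLitterError, InvalidInputError
from polaripm.lifecycle import (
    FEMALE,
    MALE,
    FEMALE_STATES,
    MALE_STATES,
    StateSpace,
    VitalRates,
    build_transition_matrix,
    joint_expectation_matrix,
    litter_thinning,
    project_population,
    stable_stage_distribution,
)

from conftest import random_rates


def enumerate_thinning(omega_L0, phi_C0):
    """Oracle: exhaustive enumeration of (litter size, survivor count)."""
    joint = np.zeros(4)  # survivors 0..3
    for k in (1, 2, 3):
        for j in range(0, k + 1):
            joint[j] += (
                omega_L0[k - 1]
                * math.comb(k, j)
                * phi_C0**j
                * (1 - phi_C0) ** (k - j)
            )
    phi_L0 = joint[1:].sum()
    omega_L1 = joint[1:] / phi_L0
    return phi_L0, omega_L1


class TestStateSpace:
    def test_counts_and_structure(self):
        f = StateSpace.for_sex(FEMALE)
        m = StateSpace.for_sex(MALE)
        assert f.n_states == 13 and m.n_states == 9
        # one absorbing dead state; every live stage has in and out versions
        for sp in (f, m):
            assert sp.states[-1] == "dead"
            live = sp.states[:-1]
            assert {s.rsplit("_", 1)[1] for s in live} == {"in", "out"}
            assert len(live) == 2 * len(sp.classes)

    def test_inside_indicator(self):
        f = StateSpace.for_sex(FEMALE)
        ind = f.inside_indicator
        assert ind.sum() == len(f.classes)
        assert ind[f.index("AFNC_in")] == 1 and ind[f.index("AFNC_out")] == 0
        assert ind[f.dead_index] == 0

    def test_unknown_sex_rejected(self):
        with pytest.raises(InvalidInputError):
            StateSpace.for_sex("hermaphrodite")


class TestLitterThinning:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            w = rng.dirichlet([1, 1, 1])
            phi = float(rng.uniform(0.05, 0.99))
            lm = litter_thinning(tuple(w), phi, 0.9)
            phi_L0, omega_L1 = enumerate_thinning(w, phi)
            assert lm.phi_L0 == pytest.approx(phi_L0, abs=1e-12)
            assert np.allclose(lm.omega_L1, omega_L1, atol=1e-12)
            assert lm.l_L1 == pytest.approx(np.dot([1, 2, 3], omega_L1), abs=1e-10)

    def test_reference_values(self):
        lm = litter_thinning((0.10, 0.62, 0.28), 0.62, 0.92)
        assert lm.phi_L0 == pytest.approx(0.8571, abs=1e-4)
        assert np.allclose(lm.omega_L1, (0.5009, 0.4212, 0.0779), atol=1e-4)
        assert lm.l_L0 == pytest.approx(2.18, abs=1e-10)
        assert lm.l_L1 == pytest.approx(1.5769, abs=1e-4)

    def test_no_thinning_when_all_cubs_survive(self):
        w = (0.2, 0.5, 0.3)
        lm = litter_thinning(w, 1.0, 0.5)
        assert lm.phi_L0 == pytest.approx(1.0)
        assert np.allclose(lm.omega_L1, w)
        assert lm.l_L1 == pytest.approx(lm.l_L0)

    def test_monotone_in_cub_survival(self):
        grid = np.arange(0.1, 0.95, 0.1)
        w = (0.10, 0.62, 0.28)
        phis = [litter_thinning(w, p, 0.9) for p in grid]
        phi_L0s = [lm.phi_L0 for lm in phis]
        l_L1s = [lm.l_L1 for lm in phis]
        assert np.all(np.diff(phi_L0s) >= 0)
        assert np.all(np.diff(l_L1s) >= 0)

    def test_degenerate_and_invalid(self):
        with pytest.raises(DegenerateLitterError):
            litter_thinning((0.1, 0.6, 0.3), 0.0, 0.9)
        with pytest.raises(InvalidInputError):
            litter_thinning((0.5, 0.5, 0.5), 0.6, 0.9)


class TestTransitionMatrix:
    def test_reference_cell_products(self, modes, modes_litter):
        tf = build_transition_matrix(FEMALE, modes, modes_litter)
        tm = build_transition_matrix(MALE, modes, modes_litter)
        # survival x breeding x movement-out for a parturient female
        assert tf.prob("AFNC_in", "AFC0_out") == pytest.approx(
            0.90 * 0.83 * 0.99, abs=1e-12
        )
        assert tm.prob("AM_in", "AM_in") == pytest.approx(0.89 * 0.59, abs=1e-12)

    def test_dead_state_absorbing(self, modes, modes_litter):
        for sex in (FEMALE, MALE):
            t = build_transition_matrix(sex, modes, modes_litter)
            dead = t.space.dead_index
            col = t.theta[:, dead]
            assert col[dead] == 1.0 and col[:dead].sum() == 0.0

    def test_columns_sum_to_one_over_random_rates(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            rates = random_rates(rng)
            for sex in (FEMALE, MALE):
                t = build_transition_matrix(sex, rates)
                np.testing.assert_allclose(t.theta.sum(axis=0), 1.0, atol=1e-12)
                assert (t.theta >= -1e-15).all()

    def test_three_year_reproductive_cycle(self):
        # with certain survival, certain breeding and weaning, no re-breeding
        # after loss, the female chain cycles AFC0 -> AFC1 -> AFNC -> AFC0
        rates = VitalRates.chukchi_modes().replace(
            phi_AF=1.0, phi_SF=1.0, phi_C0=1.0, phi_C1=1.0,
            B1=1.0, B2=0.0, W=1.0, psi1_II=1.0, psi2_II=1.0,
        )
        t = build_transition_matrix(FEMALE, rates)
        assert t.prob("AFC0_in", "AFC1_in") == pytest.approx(1.0)
        assert t.prob("AFC1_in", "AFNC_in") == pytest.approx(1.0)
        assert t.prob("AFNC_in", "AFC0_in") == pytest.approx(1.0)

    def test_unknown_sex(self, modes):
        with pytest.raises(InvalidInputError):
            build_transition_matrix("unknown", modes)

    def test_text_export_roundtrip(self, modes, modes_litter, tmp_path):
        import pandas as pd

        t = build_transition_matrix(FEMALE, modes, modes_litter)
        t.to_text(tmp_path / "theta.tsv")
        back = pd.read_csv(tmp_path / "theta.tsv", sep="\t", index_col=0)
        assert list(back.columns) == list(t.space.states)
        np.testing.assert_allclose(back.to_numpy(), t.theta, atol=1e-9)


class TestProjection:
    def test_closed_deterministic_loop(self):
        rates = VitalRates.chukchi_modes().replace(
            phi_AF=1.0, phi_SF=1.0, B1=0.0, psi1_II=1.0,
        )
        tf = build_transition_matrix(FEMALE, rates)
        tm = build_transition_matrix(MALE, rates)
        from polaripm.lifecycle import litter_thinning as lt

        litter = lt(rates.omega_L0, rates.phi_C0, rates.phi_C1)
        nf = np.zeros(13, dtype=int)
        nf[FEMALE_STATES.index("AFNC_in")] = 10
        nm = np.zeros(9, dtype=int)
        f2, m2 = project_population(nf, nm, tf, tm, litter, rates,
                                    np.random.default_rng(0))
        assert f2[FEMALE_STATES.index("AFNC_in")] == 10
        assert m2.sum() == 0

    def test_binomial_expectation_adult_males(self, modes, modes_litter):
        tf = build_transition_matrix(FEMALE, modes, modes_litter)
        tm = build_transition_matrix(MALE, modes, modes_litter)
        nm = np.zeros(9, dtype=int)
        nm[MALE_STATES.index("AM_in")] = 10_000
        _, m2 = project_population(
            np.zeros(13, int), nm, tf, tm, modes_litter, modes,
            np.random.default_rng(123),
        )
        expected = 10_000 * 0.89 * 0.59
        sd = np.sqrt(10_000 * 0.5251 * (1 - 0.5251))
        assert abs(m2[MALE_STATES.index("AM_in")] - expected) < 4 * sd

    def test_mean_projection_matches_expectation_matrix(self, modes, modes_litter):
        tf = build_transition_matrix(FEMALE, modes, modes_litter)
        tm = build_transition_matrix(MALE, modes, modes_litter)
        rng = np.random.default_rng(99)
        nf = np.zeros(13, dtype=int)
        nm = np.zeros(9, dtype=int)
        for s, c in (("AFNC_in", 40), ("AFC1_in", 30), ("AFC1_out", 30),
                     ("F2Y_in", 20)):
            nf[FEMALE_STATES.index(s)] = c
        nm[MALE_STATES.index("AM_in")] = 50
        reps = 1000
        acc_f = np.zeros(13)
        acc_m = np.zeros(9)
        for _ in range(reps):
            f2, m2 = project_population(nf, nm, tf, tm, modes_litter, modes, rng)
            acc_f += f2
            acc_m += m2
        acc_f /= reps
        acc_m /= reps
        A, labels = joint_expectation_matrix(modes, modes_litter)
        n0 = np.concatenate([nf[:-1], nm[:-1]]).astype(float)
        expect = A @ n0
        got = np.concatenate([acc_f[:-1], acc_m[:-1]])
        # Monte-Carlo error: ~4 x sqrt(var/reps), var at most binomial scale
        tol = 4.0 * np.sqrt(np.maximum(expect, 1.0) / reps) + 0.05
        assert np.all(np.abs(got - expect) < tol)

    def test_negative_counts_rejected(self, modes, modes_litter):
        tf = build_transition_matrix(FEMALE, modes, modes_litter)
        tm = build_transition_matrix(MALE, modes, modes_litter)
        nf = np.zeros(13, int)
        nf[0] = -1
        with pytest.raises(InvalidInputError):
            project_population(nf, np.zeros(9, int), tf, tm, modes_litter,
                               modes, np.random.default_rng(0))

    def test_longrun_growth_matches_dominant_eigenvalue(self, modes, modes_litter):
        A, _ = joint_expectation_matrix(modes, modes_litter)
        lam, stable = stable_stage_distribution(A)
        rng = np.random.default_rng(2024)
        tf = build_transition_matrix(FEMALE, modes, modes_litter)
        tm = build_transition_matrix(MALE, modes, modes_litter)
        n_years, reps = 50, 10
        log_growth = []
        for _ in range(reps):
            n0 = np.round(2000 * stable).astype(int)
            nf = np.append(n0[:12], 0)
            nm = np.append(n0[12:], 0)
            start = nf[:-1].sum() + nm[:-1].sum()
            for _ in range(n_years):
                nf, nm = project_population(nf, nm, tf, tm, modes_litter,
                                            modes, rng)
            end = nf[:-1].sum() + nm[:-1].sum()
            log_growth.append(np.log(end / start) / n_years)
        mc_se = np.std(log_growth, ddof=1) / np.sqrt(reps)
        assert np.mean(log_growth) == pytest.approx(
            np.log(lam), abs=max(4 * mc_se, 0.004)
        )
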