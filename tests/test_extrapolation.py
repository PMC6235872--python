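"""Closure correction, habitat-weighted extrapolation, AFC0 add-back."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from polaripm.exceptions import InvalidInputError
from polaripm.extrapolation import (
    DensityExtrapolation,
    HabitatGrid,
    UseAreas,
    add_dependent_c0,
    afc0_addback_factor,
    compute_qhat,
    density_from_study,
    extrapolate_abundance,
    removal_rate_report,
    stationary_reproductive_distribution,
)
from polaripm.lifecycle import VitalRates


def uniform_grid(n_sampling=4, n_total=40, h=1.0):
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n_total)],
        "h": h * np.ones(n_total),
        "in_sampling": [1] * n_sampling + [0] * (n_total - n_sampling),
        "in_cs": [1] * n_total,
    })
    return HabitatGrid(cells)


class TestUseAreas:
    def test_qhat_is_mean_proportion(self):
        ua = UseAreas(pd.Series({"a": 0.2, "b": 0.3}))
        assert ua.qhat == pytest.approx(0.25)

    def test_all_locations_inside(self):
        square = box(0, 0, 10, 10)
        locs = pd.DataFrame({"id": ["a"] * 3, "timestamp": 0,
                             "x": [1, 2, 3], "y": [1, 2, 3]})
        assert compute_qhat(locs, square).qhat == 1.0

    def test_empty_polygon_gives_zero(self):
        square = box(0, 0, 1, 1)
        locs = pd.DataFrame({"id": ["a", "b"], "timestamp": 0,
                             "x": [5.0, 9.0], "y": [5.0, 9.0]})
        assert compute_qhat(locs, square).qhat == 0.0

    def test_wkt_accepted(self):
        locs = pd.DataFrame({"id": ["a", "a"], "timestamp": 0,
                             "x": [0.5, 5.0], "y": [0.5, 5.0]})
        ua = compute_qhat(locs, box(0, 0, 1, 1).wkt)
        assert ua.qhat == pytest.approx(0.5)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(InvalidInputError):
            UseAreas(pd.Series({"a": 1.2}))


class TestDensity:
    def test_reported_magnitude(self):
        # study-area abundance 296, closure 0.25, 25,000 km^2 core area
        d = density_from_study(296, 0.25, 25_000)
        assert float(d) == pytest.approx(0.00296, rel=1e-12)
        assert float(f"{float(d):.2g}") == 0.0030

    def test_trivial_cases(self):
        assert float(density_from_study(0, 0.7, 100)) == 0.0
        assert float(density_from_study(100, 1.0, 100)) == 1.0
        with pytest.raises(InvalidInputError):
            density_from_study(10, 0.5, 0)


class TestExtrapolation:
    def test_uniform_habitat_cell_ratio(self):
        grid = uniform_grid(n_sampling=4, n_total=40)
        # D* x A = 74 with ten times the habitat mass outside
        n = extrapolate_abundance(74 / 25_000.0, 25_000.0, grid)
        assert float(n) == pytest.approx(740.0)

    def test_identity_when_masks_equal(self):
        grid = uniform_grid(n_sampling=6, n_total=6)
        n = extrapolate_abundance(0.004, 25_000.0, grid)
        assert float(n) == pytest.approx(0.004 * 25_000.0)

    def test_invariant_to_habitat_rescaling(self):
        rng = np.random.default_rng(3)
        cells = pd.DataFrame({
            "cell_id": range(30),
            "h": rng.lognormal(0, 1, 30),
            "in_sampling": [1] * 5 + [0] * 25,
            "in_cs": [1] * 30,
        })
        g1 = HabitatGrid(cells)
        g2 = HabitatGrid(cells.assign(h=cells["h"] * 17.3))
        a = extrapolate_abundance(0.003, 25_000, g1)
        b = extrapolate_abundance(0.003, 25_000, g2)
        assert float(a) == pytest.approx(float(b), rel=1e-12)

    def test_invariant_to_cell_relabeling(self):
        rng = np.random.default_rng(4)
        cells = pd.DataFrame({
            "cell_id": range(20),
            "h": rng.lognormal(0, 1, 20),
            "in_sampling": [1] * 4 + [0] * 16,
            "in_cs": [1] * 20,
        })
        shuffled = cells.sample(frac=1, random_state=1).reset_index(drop=True)
        a = extrapolate_abundance(0.003, 25_000, HabitatGrid(cells))
        b = extrapolate_abundance(0.003, 25_000, HabitatGrid(shuffled))
        assert float(a) == pytest.approx(float(b), rel=1e-12)

    def test_zero_sampling_habitat_rejected(self):
        cells = pd.DataFrame({
            "cell_id": [0, 1], "h": [0.0, 1.0],
            "in_sampling": [1, 0], "in_cs": [1, 1],
        })
        with pytest.raises(InvalidInputError, match="zero habitat"):
            HabitatGrid(cells)

    def test_sampling_outside_boundary_rejected(self):
        cells = pd.DataFrame({
            "cell_id": [0, 1], "h": [1.0, 1.0],
            "in_sampling": [1, 1], "in_cs": [1, 0],
        })
        with pytest.raises(InvalidInputError, match="boundary"):
            HabitatGrid(cells)


class TestAfc0AddBack:
    def test_hand_solvable_cycle(self):
        # certain breeding/litter survival/weaning: the reproductive chain
        # cycles AFNC -> AFC0 -> AFC1 -> AFNC, stationary AFC0 share 1/3
        rates = VitalRates.chukchi_modes().replace(
            B1=1.0, phi_C0=1.0, phi_C1=1.0, W=1.0,
        )
        pi = stationary_reproductive_distribution(rates)
        assert pi["AFC0"] == pytest.approx(1.0 / 3.0, abs=1e-9)
        assert pi["AFC2"] == pytest.approx(0.0, abs=1e-9)

    def test_no_breeding_no_addback(self):
        rates = VitalRates.chukchi_modes().replace(B1=0.0, B2=0.0)
        assert float(add_dependent_c0(1000.0, rates)) == pytest.approx(1000.0)

    def test_monotone_in_breeding_probability(self):
        base = VitalRates.chukchi_modes()
        vals = [
            afc0_addback_factor(base.replace(B1=b1))
            for b1 in (0.2, 0.4, 0.6, 0.8)
        ]
        assert np.all(np.diff(vals) > 0)

    def test_addback_positive_at_point_estimates(self, modes):
        f = afc0_addback_factor(modes)
        assert 0.0 < f < 1.0


class TestRemovalRate:
    def test_reported_bounds(self):
        # 24 + 32 = 56 removals/year against the abundance interval
        rep = removal_rate_report(56, (2937, 1552, 5944))
        assert rep["high_pct"] == pytest.approx(3.6, abs=0.05)
        assert rep["low_pct"] == pytest.approx(0.9, abs=0.05)
        assert rep["point_pct"] == pytest.approx(1.9, abs=0.1)

    def test_zero_removals(self):
        assert removal_rate_report(0, 1000.0)["point_pct"] == 0.0

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(InvalidInputError):
            removal_rate_report(10, 0.0)


class TestPipeline:
    def test_full_pipeline_summaries(self, short_fit):
        from polaripm.simulate import synthetic_extrapolation_inputs

        locs, wkt, grid = synthetic_extrapolation_inputs(seed=8)
        ua = compute_qhat(locs, wkt)
        assert 0.05 < ua.qhat < 0.6
        ex = DensityExtrapolation(short_fit, ua, grid)
        res = ex.run(seed=1, max_draws=400)
        # N_CS >= N*_CS (AFC0/C0 add-back only adds bears)
        assert res.n_cs[0] >= res.n_star_cs[0]
        assert res.d_sampling[0] > 0
        summ = res.summary()
        assert set(summ.index) == {
            "D_sampling", "D_star_sampling", "N_star_CS", "N_CS",
            "D_CS_boundary",
        }

    def test_bootstrap_se_shrinks_with_draws(self, short_fit):
        from polaripm.simulate import synthetic_extrapolation_inputs

        locs, wkt, grid = synthetic_extrapolation_inputs(seed=8)
        ua = compute_qhat(locs, wkt)
        ex = DensityExtrapolation(short_fit, ua, grid)
        ses = [ex.bootstrap_se(n, n_boot=60, seed=4) for n in (25, 100, 400)]
        assert ses[2] < ses[0]
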