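"""Biweekly vegetation dynamics: growth, mortality, dispersal, establishment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import savhyd.vegetation as veg_mod
from savhyd.vegetation import (
    VegState,
    disperse,
    end_season_mortality,
    establish,
    grow,
    initial_veg_state,
    step_biweek,
)


class TestGrow:
    def test_no_water_no_growth(self):
        d = grow(np.array([[0.3]]), np.array([[0.0]]), np.array([0.5]),
                 np.array([0.1]), np.array([1.0]))
        assert d.sum() == 0.0

    def test_no_space_no_growth(self):
        d = grow(np.array([[0.3]]), np.array([[10.0]]), np.array([0.5]),
                 np.array([0.1]), np.array([0.0]))
        assert d.sum() == 0.0

    def test_closed_form(self):
        # t_veg 0.5, wue 0.01/mm, 10 mm transpired, full free space -> 0.05,
        # below the 0.1 biweekly cap
        d = grow(np.array([[0.3]]), np.array([[10.0]]), np.array([0.5]),
                 np.array([0.1]), np.array([1.0]), wue=0.01)
        assert abs(d[0, 0] - 0.05) < 1e-15

    def test_cap_binds(self):
        d = grow(np.array([[0.3]]), np.array([[1000.0]]), np.array([0.5]),
                 np.array([0.1]), np.array([1.0]), wue=0.01)
        assert d[0, 0] == 0.1


class TestEndSeasonMortality:
    def test_immortal_limit(self):
        c = end_season_mortality(np.array([[0.4]]), np.array([[0.0]]),
                                 np.array([0.0]), np.array([False]))
        assert c[0, 0] == 0.4

    def test_full_stress_algebra(self):
        c = end_season_mortality(np.array([[0.5]]), np.array([[1.0]]),
                                 np.array([0.54]), np.array([False]))
        assert abs(c[0, 0] - 0.5 * (1 - 0.54)) < 1e-15

    def test_background_share(self):
        c = end_season_mortality(np.array([[0.5]]), np.array([[0.0]]),
                                 np.array([0.54]), np.array([False]), b0=0.2)
        assert abs(c[0, 0] - 0.5 * (1 - 0.54 * 0.2)) < 1e-15

    def test_annuals_always_die_back(self):
        c = end_season_mortality(np.array([[0.5]]), np.array([[0.0]]),
                                 np.array([0.0]), np.array([True]))
        assert c[0, 0] == 0.0


class TestDisperse:
    def test_absent_type_produces_no_seed(self, grazing_strategies, rng):
        veg = initial_veg_state(grazing_strategies, 6, 6)
        veg.cover[:] = 0.0
        out = disperse(veg, grazing_strategies, 40.0, rng)
        assert out.sum() == 0.0

    def test_uniform_grass_field_is_fixed_point(self, grazing_strategies, rng):
        veg = initial_veg_state(grazing_strategies, 6, 6)
        grass = ~grazing_strategies.is_shrub
        veg.cover[:] = 0.0
        veg.cover[..., grass] = 0.03
        out = disperse(veg, grazing_strategies, 40.0, rng)
        np.testing.assert_allclose(out[..., grass], 0.03, atol=1e-12)

    def test_long_distance_rate_scales_with_animal_density(self, grazing_strategies):
        # expected event count at SR 10 is 5x the count at SR 50
        counts = {}
        for sr in (10.0, 50.0):
            total = 0.0
            for seed in range(200):
                rng = np.random.default_rng(seed)
                veg = initial_veg_state(grazing_strategies, 6, 6)
                base = disperse(veg, grazing_strategies, float("inf"),
                                np.random.default_rng(seed))
                out = disperse(veg, grazing_strategies, sr, rng)
                total += (out - base).sum()
            counts[sr] = total
        assert counts[10.0] > 0
        assert abs(counts[10.0] / counts[50.0] - 5.0) < 0.8

    def test_nonpositive_sr_rejected(self, grazing_strategies, rng):
        veg = initial_veg_state(grazing_strategies, 4, 4)
        with pytest.raises(ValueError):
            disperse(veg, grazing_strategies, 0.0, rng)


class TestEstablish:
    def test_dry_soil_blocks_establishment(self, grazing_strategies, rng):
        T = len(grazing_strategies)
        out = establish(np.ones((4, 4, T)), np.full((4, 4), 0.05),
                        np.ones((4, 4)), grazing_strategies, rng)
        assert out.sum() == 0.0

    def test_no_free_space_blocks_establishment(self, grazing_strategies, rng):
        T = len(grazing_strategies)
        out = establish(np.ones((4, 4, T)), np.full((4, 4), 0.12),
                        np.zeros((4, 4)), grazing_strategies, rng)
        assert out.sum() == 0.0

    def test_expected_increment_matches_rate(self, grazing_strategies):
        # perennial types: expectation p_est * seed_bank * free over the
        # stochastic rounding, estimated over many seeds
        strat = grazing_strategies
        T = len(strat)
        p_est = np.full(T, 0.05)
        total = 0.0
        n_draws = 300
        per0 = int(np.flatnonzero(strat.is_perennial)[0])
        for seed in range(n_draws):
            bank = np.zeros((2, 2, T))
            bank[..., per0] = 1.0
            out = establish(bank, np.full((2, 2), 0.12), np.ones((2, 2)),
                            strat, np.random.default_rng(seed), p_est=p_est)
            total += out[..., per0].mean()
        assert abs(total / n_draws - 0.05) < 0.005


class TestStepBiweek:
    def _zero_inputs(self, strat, rows=5, cols=5):
        T = len(strat)
        return np.zeros((rows, cols, T)), np.full((rows, cols), 0.12)

    def test_empty_landscape_is_absorbing(self, grazing_strategies, rng):
        veg = initial_veg_state(grazing_strategies, 5, 5)
        veg.cover[:] = 0.0
        veg.seed_bank[:] = 0.0
        transp, theta = self._zero_inputs(grazing_strategies)
        step_biweek(veg, transp, theta, grazing_strategies, 40.0, rng)
        assert veg.cover.sum() == 0.0

    def test_unstressed_single_type_grows(self, grazing_strategies, rng):
        strat = grazing_strategies
        veg = initial_veg_state(strat, 5, 5)
        per0 = int(np.flatnonzero(strat.is_perennial)[0])
        veg.cover[:] = 0.0
        veg.cover[..., per0] = 0.2
        veg.seed_bank = veg.cover.copy()
        transp, theta = self._zero_inputs(strat)
        transp[..., per0] = 8.0
        before = veg.cover[..., per0].sum()
        step_biweek(veg, transp, theta, strat, 40.0, rng)
        assert veg.cover[..., per0].sum() > before

    def test_total_cover_never_exceeds_one(self, grazing_strategies):
        strat = grazing_strategies
        rng = np.random.default_rng(9)
        veg = initial_veg_state(strat, 5, 5)
        veg.cover *= 4.0   # near-saturated landscape
        veg.cover /= np.maximum(veg.cover.sum(-1, keepdims=True), 1.0) * 1.01
        T = len(strat)
        for _ in range(10):
            transp = rng.random((5, 5, T)) * 10
            step_biweek(veg, transp, np.full((5, 5), 0.12), strat, 40.0, rng)
            assert veg.cover.sum(axis=-1).max() <= 1.0 + 1e-9
            assert veg.cover.min() >= 0.0

    def test_water_advantage_wins_cover(self, soil):
        """Two otherwise identical types, one with doubled uptake, sharing
        limited water: the stronger competitor gains more cover."""
        from savhyd.hydrology import CellHydroState, step_day
        from savhyd.strategies import META_DEFAULTS, StrategySet, StrategyType

        m = META_DEFAULTS["perennial"]
        mk = lambda uid, up: StrategyType(uid, m, m.t_veg, m.mrd, None, None, up, 0.077)
        strat = StrategySet([mk("hi", 0.9), mk("lo", 0.45)])
        rows = cols = 4
        veg = VegState(cover=np.full((rows, cols, 2), 0.1),
                       seed_bank=np.full((rows, cols, 2), 0.1))
        state = CellHydroState.initial(rows * cols, soil)
        rng = np.random.default_rng(0)
        for bw in range(10):
            transp = np.zeros((rows * cols, 2))
            for day in range(14):
                fl = step_day(state, 5.0 if day % 4 == 0 else 0.0, 26.0,
                              (bw * 14 + day) % 365,
                              veg.cover.reshape(-1, 2), strat, soil)
                transp += fl["transp_upper"] + fl["transp_lower"]
            step_biweek(veg, transp.reshape(rows, cols, 2),
                        np.full((rows, cols), state.theta_upper.mean()),
                        strat, 40.0, rng)
        gained = veg.cover.mean(axis=(0, 1)) - 0.1
        assert gained[0] > gained[1]

    def test_invariant_violation_rejected(self, grazing_strategies, rng):
        veg = initial_veg_state(grazing_strategies, 3, 3)
        veg.cover[0, 0, 0] = 2.0
        transp, theta = self._zero_inputs(grazing_strategies, 3, 3)
        with pytest.raises(ValueError):
            step_biweek(veg, transp, theta, grazing_strategies, 40.0, rng)


@given(st.integers(0, 10_000))
def test_mortality_never_negative(seed):
    rng = np.random.default_rng(seed)
    cover = rng.random((3, 4))
    stress = rng.random((3, 4))
    mrd = rng.random(4)
    out = end_season_mortality(cover, stress, mrd, np.zeros(4, bool))
    assert out.min() >= 0.0
    assert np.all(out <= cover + 1e-12)
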