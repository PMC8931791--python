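"""Diversity, effect-size, trait-space and water-use metrics vs brute force."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from savhyd.metrics import (
    TraitSpace,
    cluster_wcss,
    cohens_d,
    epsilon_squared,
    factor_structure,
    functional_dispersion,
    richness,
    shannon_pielou,
    water_use,
    wet_season_moisture,
)


class TestRichness:
    def test_direct_application(self):
        assert richness({"A": 10.0, "B": 2.0, "C": 3.0}) == 2

    def test_all_zero(self):
        assert richness(np.zeros(5)) == 0

    def test_threshold_is_strict(self):
        assert richness(np.array([2.5])) == 0
        assert richness(np.array([2.5000001])) == 1


class TestShannonPielou:
    def test_even_community_maximally_even(self):
        d = shannon_pielou(np.full(5, 20.0))
        assert d.J == pytest.approx(1.0)
        assert d.H == pytest.approx(np.log(5))

    def test_single_type_degenerate(self):
        d = shannon_pielou(np.array([50.0, 0.1]))
        assert d.S == 1 and d.H == 0.0 and d.J == 0.0

    def test_hand_evaluated_example(self):
        d = shannon_pielou(np.array([50.0, 25.0, 25.0]))
        assert d.H == pytest.approx(1.039721, abs=1e-6)
        assert d.J == pytest.approx(0.946395, abs=1e-6)

    @given(st.floats(0.1, 100.0))
    def test_evenness_invariant_to_rescaling(self, scale):
        # with the cover threshold disabled, J depends only on proportions
        a = np.array([40.0, 25.0, 10.0, 5.0])
        assert shannon_pielou(a * scale, threshold_pct=0.0).J == pytest.approx(
            shannon_pielou(a, threshold_pct=0.0).J, rel=1e-9
        )

    @given(st.integers(0, 1_000))
    def test_uniform_maximises_entropy(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(3.0, 50.0, size=6)
        assert shannon_pielou(a).H <= np.log(6) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_pielou(np.zeros(3))


class TestEpsilonSquared:
    def test_null_statistic(self):
        e2, label = epsilon_squared(0.0, 30)
        assert e2 == 0.0 and label == "small"

    def test_large_label_above_cut(self):
        n = 100
        h = 0.27 * (n**2 - 1) / (n + 1)
        _, label = epsilon_squared(h, n)
        assert label == "large"

    def test_two_group_rank_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([10.0, 11.0, 12.0, 13.0])
        h = stats.kruskal(x, y).statistic
        n = 8
        e2, _ = epsilon_squared(h, n)
        assert e2 == pytest.approx(h / ((n**2 - 1) / (n + 1)), rel=1e-12)
        assert 0.0 <= e2 <= 1.0 + 1e-9

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            epsilon_squared(1.0, 1)


class TestCohensD:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x, x) == 0.0

    def test_unit_case(self):
        rng = np.random.default_rng(4)
        x = rng.normal(1.0, 1.0, 20_000)
        y = rng.normal(0.0, 1.0, 20_000)
        assert cohens_d(x, y) == pytest.approx(1.0, abs=0.05)

    def test_arithmetic_oracle(self):
        x = np.array([3.0, 5.0, 7.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        nx, ny = 3, 4
        pooled = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (
            nx + ny - 2
        )
        want = (x.mean() - y.mean()) / np.sqrt(pooled)
        assert cohens_d(x, y) == pytest.approx(want, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d(np.ones(3), np.ones(3))


class TestFunctionalDispersion:
    def test_point_community(self):
        space = TraitSpace(np.array([[1.0, 2.0], [5.0, 5.0]]), np.array([3.0, 0.0]))
        assert functional_dispersion(space) == 0.0

    def test_two_equal_types_half_distance(self):
        space = TraitSpace(np.array([[0.0, 0.0], [3.0, 4.0]]), np.array([1.0, 1.0]))
        assert functional_dispersion(space) == pytest.approx(2.5)

    @given(st.integers(0, 2_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(5, 3))
        w = rng.uniform(0.1, 2.0, 5)
        space = TraitSpace(coords, w)
        centroid = sum(w[i] * coords[i] for i in range(5)) / w.sum()
        brute = sum(w[i] * np.linalg.norm(coords[i] - centroid) for i in range(5)) / w.sum()
        assert functional_dispersion(space) == pytest.approx(brute, abs=1e-12)

    @given(st.floats(0.0, 2 * np.pi))
    def test_invariant_under_rotation_and_translation(self, angle):
        rng = np.random.default_rng(12)
        coords = rng.normal(size=(6, 2))
        w = rng.uniform(0.5, 1.5, 6)
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = coords @ R.T + np.array([3.0, -1.0])
        assert functional_dispersion(TraitSpace(moved, w)) == pytest.approx(
            functional_dispersion(TraitSpace(coords, w)), rel=1e-9
        )

    def test_no_abundance_rejected(self):
        with pytest.raises(ValueError):
            functional_dispersion(TraitSpace(np.ones((2, 2)), np.zeros(2)))


class TestFactorStructure:
    def _blocks(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        driver = rng.normal(size=n)
        block_a = driver[:, None] + 0.05 * rng.normal(size=(n, 3))
        block_b = -driver[:, None] + 0.05 * rng.normal(size=(n, 3))
        return np.hstack([block_a, block_b])

    def test_anticorrelated_blocks_separate_on_factor_one(self):
        X = self._blocks()
        orient = np.array([True] * 3 + [False] * 3)
        loadings, eigvals, retained, kept = factor_structure(X, orient_positive=orient)
        assert loadings[:3, 0].min() > 0.9
        assert loadings[3:, 0].max() < -0.9

    def test_eigenvalue_retention_rule(self):
        X = self._blocks()
        _, eigvals, retained, _ = factor_structure(X)
        assert retained == min(2, int((eigvals > 1).sum()))

    def test_rank_one_structure_retains_single_factor(self):
        rng = np.random.default_rng(3)
        driver = rng.normal(size=300)
        X = driver[:, None] + 0.01 * rng.normal(size=(300, 4))
        _, _, retained, _ = factor_structure(X)
        assert retained == 1

    def test_constant_columns_dropped_with_warning(self):
        X = self._blocks()
        X = np.hstack([X, np.full((X.shape[0], 1), 7.0)])
        with pytest.warns(UserWarning):
            loadings, _, _, kept = factor_structure(X)
        assert loadings.shape[0] == 6
        assert 6 not in kept

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            factor_structure(np.ones((10, 3)))


class TestClusterWcss:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.05, size=(8, 2))
        b = rng.normal(5.0, 0.05, size=(8, 2))
        labels, wcss = cluster_wcss(np.vstack([a, b]), k=2)
        assert len(set(labels[:8])) == 1
        assert len(set(labels[8:])) == 1
        assert labels[0] != labels[8]

    def test_identical_points_zero_wcss(self):
        labels, wcss = cluster_wcss(np.ones((5, 2)), k=2)
        assert wcss.sum() == pytest.approx(0.0, abs=1e-12)

    def test_wcss_matches_definition(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 2))
        labels, wcss = cluster_wcss(pts, k=2)
        for j in range(2):
            grp = pts[labels == j]
            brute = ((grp - grp.mean(axis=0)) ** 2).sum()
            assert wcss[j] == pytest.approx(brute, abs=1e-9)

    def test_total_wcss_non_increasing_in_k(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(15, 2))
        totals = [cluster_wcss(pts, k=k)[1].sum() for k in (1, 2, 3)]
        assert totals[0] >= totals[1] >= totals[2]

    def test_k_exceeding_points_rejected(self):
        with pytest.raises(ValueError):
            cluster_wcss(np.ones((2, 2)), k=3)


class TestWaterUse:
    def test_edge_cases(self):
        assert water_use(0.0, 10.0) == 0.0
        assert water_use(5.0, 5.0) == 100.0
        assert water_use(0.0, 0.0) == 0.0

    def test_arithmetic(self):
        assert water_use(44.2, 50.0) == pytest.approx(88.4)

    def test_transpiration_exceeding_et_rejected(self):
        with pytest.raises(ValueError):
            water_use(6.0, 5.0)


class TestWetSeasonMoisture:
    def test_constant_series(self):
        assert wet_season_moisture(np.full(365, 11.4), (100, 200)) == pytest.approx(11.4)

    def test_no_wet_season(self):
        assert wet_season_moisture(np.ones(365), None) is None

    def test_hand_built_window(self):
        series = np.zeros(365)
        series[10:20] = np.arange(10.0)
        assert wet_season_moisture(series, (10, 19)) == pytest.approx(4.5)
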