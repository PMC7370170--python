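"""Within-radius neighbor counts: oracles, invariances, effect recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flyspace.arena import DensityRangeWarning, PointConfig
from flyspace.socialspace import (
    count_within_radius,
    nearest_neighbor_distances,
    pairwise_distances,
    recover_interaction_strength,
)
from flyspace.synthetic import sample_csr


def brute_force_counts(coords: np.ndarray, radius: float) -> np.ndarray:
    """Independent O(n^2) double-loop oracle for the within-radius count."""
    n = len(coords)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx = coords[i][0] - coords[j][0]
            dy = coords[i][1] - coords[j][1]
            if (dx * dx + dy * dy) ** 0.5 <= radius:
                counts[i] += 1
    return counts


def _config(coords, **kw):
    return PointConfig(coords=np.asarray(coords, dtype=float), **kw)


class TestPairwiseDistances:
    def test_three_four_five(self):
        d = pairwise_distances(_config([(0, 0), (3, 4)]))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[1, 0] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_empty(self):
        assert pairwise_distances(_config(np.empty((0, 2)))).shape == (0, 0)

    def test_matches_double_loop(self, rng):
        coords = rng.uniform(0, 50, size=(10, 2))
        d = pairwise_distances(_config(coords))
        for i in range(10):
            for j in range(10):
                expected = np.hypot(*(coords[i] - coords[j]))
                assert d[i, j] == pytest.approx(expected, abs=1e-12)


class TestCountWithinRadius:
    def test_all_isolated(self):
        xs = [(20 * i, 20 * j) for i in range(4) for j in range(4)]
        res = count_within_radius(_config(xs), radius_mm=10.0)
        assert (res.per_fly_counts == 0).all()
        assert res.replicate_mean == 0.0

    def test_collinear_hand_geometry(self):
        with pytest.warns(DensityRangeWarning):
            res = count_within_radius(_config([(0, 0), (8, 0), (16, 0)]), radius_mm=10.0)
        np.testing.assert_array_equal(res.per_fly_counts, [1, 2, 1])
        assert res.replicate_mean == pytest.approx(4.0 / 3.0)

    def test_default_radius_is_four_body_lengths(self):
        cfg = _config([(0, 0), (9.9, 0)], body_length=2.5)
        with pytest.warns(DensityRangeWarning):
            res = count_within_radius(cfg)
        assert res.radius_mm == 10.0
        assert (res.per_fly_counts == 1).all()

    def test_boundary_inclusive(self):
        with pytest.warns(DensityRangeWarning):
            res = count_within_radius(_config([(0, 0), (10, 0)]), radius_mm=10.0)
        assert (res.per_fly_counts == 1).all()

    def test_single_fly_counts_zero(self):
        with pytest.warns(DensityRangeWarning):
            res = count_within_radius(_config([(5, 5)]), radius_mm=10.0)
        np.testing.assert_array_equal(res.per_fly_counts, [0])

    def test_zero_flies_fails(self):
        with pytest.raises(ValueError, match="no focal flies"):
            count_within_radius(_config(np.empty((0, 2))))

    def test_no_warning_in_assay_range(self, arena, recwarn):
        count_within_radius(sample_csr(arena, 16, seed=0))
        assert not [w for w in recwarn if issubclass(w.category, DensityRangeWarning)]

    def test_oracle_equivalence_random_configs(self, arena):
        for seed in range(50):
            pc = sample_csr(arena, 13 + seed % 5, hardcore=1.0, seed=seed)
            res = count_within_radius(pc, radius_mm=10.0)
            np.testing.assert_array_equal(
                res.per_fly_counts, brute_force_counts(pc.coords, 10.0)
            )
            assert res.replicate_mean == pytest.approx(res.per_fly_counts.mean())

    def test_symmetry_of_neighbor_relation(self, arena):
        pc = sample_csr(arena, 16, hardcore=1.0, seed=3)
        d = pairwise_distances(pc)
        within = (d <= 10.0) & ~np.eye(16, dtype=bool)
        np.testing.assert_array_equal(within, within.T)

    def test_monotone_in_radius(self, arena):
        pc = sample_csr(arena, 16, hardcore=1.0, seed=8)
        counts = [
            count_within_radius(pc, radius_mm=r).per_fly_counts
            for r in (2.0, 5.0, 10.0, 20.0, 40.0)
        ]
        for a, b in zip(counts, counts[1:]):
            assert (b >= a).all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=10.0), seed=st.integers(0, 100))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 60, size=(14, 2))
        base = count_within_radius(_config(coords), radius_mm=10.0)
        scaled = count_within_radius(_config(coords * scale), radius_mm=10.0 * scale)
        np.testing.assert_array_equal(base.per_fly_counts, scaled.per_fly_counts)


class TestNearestNeighborDistances:
    def test_pair(self):
        np.testing.assert_allclose(
            nearest_neighbor_distances(_config([(0, 0), (5, 0)])), [5.0, 5.0]
        )

    def test_equilateral_triangle(self):
        s = 7.0
        coords = [(0, 0), (s, 0), (s / 2, s * np.sqrt(3) / 2)]
        np.testing.assert_allclose(nearest_neighbor_distances(_config(coords)), [s] * 3)

    def test_matches_brute_force(self, arena):
        pc = sample_csr(arena, 15, hardcore=1.0, seed=21)
        d = pairwise_distances(pc)
        np.fill_diagonal(d, np.inf)
        expected = [min(d[i]) for i in range(15)]
        np.testing.assert_allclose(nearest_neighbor_distances(pc), expected)

    def test_fewer_than_two_fails(self):
        with pytest.raises(ValueError):
            nearest_neighbor_distances(_config([(0, 0)]))


class TestRecoverInteractionStrength:
    def test_antisymmetry(self, rng):
        a = rng.normal(3.0, 0.5, size=9)
        b = rng.normal(2.0, 0.5, size=9)
        fwd = recover_interaction_strength(a, b, n_permutations=500, seed=0)
        rev = recover_interaction_strength(b, a, n_permutations=500, seed=0)
        assert fwd.effect == pytest.approx(-rev.effect)
        assert fwd.direction == -rev.direction == 1

    def test_identical_replicates_give_p_one(self):
        vals = np.arange(9, dtype=float)
        res = recover_interaction_strength(vals, vals.copy(), n_permutations=500, seed=1)
        assert res.p_value == 1.0
        assert res.effect == 0.0

    def test_too_few_replicates(self):
        with pytest.raises(ValueError, match=">= 5 replicates"):
            recover_interaction_strength([1, 2, 3], [1, 2, 3, 4, 5])

    def test_type_i_error_calibrated_under_null(self, arena):
        # both conditions CSR: rejection rate ~ alpha
        rejections = 0
        n_runs = 1000
        for run in range(n_runs):
            means = [
                count_within_radius(
                    sample_csr(arena, 16, hardcore=2.0, seed=run * 18 + k)
                ).replicate_mean
                for k in range(18)
            ]
            res = recover_interaction_strength(
                means[:9], means[9:], n_permutations=999, seed=run
            )
            rejections += res.p_value < 0.05
        assert abs(rejections / n_runs - 0.05) < 0.02

    def test_planted_effect_detected_with_power(self, arena):
        import warnings

        from flyspace.synthetic import InteractionParams, sample_interaction

        p5 = InteractionParams(attraction_strength=5.0)
        hits = 0
        n_runs = 100
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for run in range(n_runs):
                clustered = [
                    count_within_radius(
                        sample_interaction(arena, p5, n_sweeps=20, seed=run * 20 + k)
                    ).replicate_mean
                    for k in range(9)
                ]
                null = [
                    count_within_radius(
                        sample_csr(arena, 16, hardcore=2.0, seed=100_000 + run * 20 + k)
                    ).replicate_mean
                    for k in range(9)
                ]
                res = recover_interaction_strength(
                    clustered, null, n_permutations=999, seed=run
                )
                hits += (res.p_value < 0.05) and res.direction == 1
        assert hits / n_runs > 0.8
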