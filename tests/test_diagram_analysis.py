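"""Thresholds, Wasserstein distances, silhouettes, fractal dimension."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrintda import (
    PersistenceDiagram,
    ThresholdBand,
    apply_threshold,
    compute_threshold,
    distance_from_diagonal,
    fractal_dimension,
    generate_phantom,
    silhouette,
    wasserstein_distance,
)

from _oracles import brute_force_wasserstein


def diag_from_pers(pers, dim=0):
    pers = np.asarray(pers, float)
    return PersistenceDiagram(np.zeros_like(pers), pers, np.full(pers.size, dim))


def random_diagram(rng, n, dim=0):
    b = rng.random(n) * 0.6
    return PersistenceDiagram(b, b + rng.random(n) * 0.4, np.full(n, dim))


class TestThreshold:
    def test_midpoint_rule(self):
        d = diag_from_pers([0.9, 0.5, 0.1])
        assert compute_threshold([d], [2], 0) == pytest.approx(0.3)

    def test_keep_all_boundary(self):
        d = diag_from_pers([0.9, 0.5, 0.1])
        assert compute_threshold([d], [3], 0) == pytest.approx(0.05)

    def test_zero_target_excludes_everything(self):
        d = diag_from_pers([0.9, 0.5])
        t = compute_threshold([d], [0], 0)
        assert t > 0.9
        distinct, noise = apply_threshold(d, ThresholdBand(t, 0.0))
        assert len(distinct) == 0 and len(noise) == 2

    def test_mean_over_images(self):
        d1 = diag_from_pers([0.5, 0.3])  # c=1 -> t = 0.4
        d2 = diag_from_pers([0.9, 0.3])  # c=1 -> t = 0.6
        assert compute_threshold([d1, d2], [1, 1], 0) == pytest.approx(0.5)

    def test_overlong_target_warns_and_zeroes(self):
        d = diag_from_pers([0.5])
        with pytest.warns(UserWarning):
            assert compute_threshold([d], [5], 0) == 0.0

    def test_partition_preserves_multiplicity(self):
        d = diag_from_pers([0.9, 0.5, 0.1])
        distinct, noise = apply_threshold(d, ThresholdBand(0.3, 0.0))
        assert len(distinct) == 2 and len(noise) == 1
        assert len(distinct) + len(noise) == len(d)

    @given(st.integers(1, 12), st.integers(0, 12))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_calibration_exact_for_distinct_persistences(self, n, c):
        """On a single image with distinct persistences, threshold + apply
        recovers exactly the target feature count."""
        c = min(c, n)
        rng = np.random.default_rng(n * 100 + c)
        pers = rng.permutation(np.linspace(0.05, 0.95, n))
        d = diag_from_pers(pers)
        t = compute_threshold([d], [c], 0)
        distinct, _ = apply_threshold(d, ThresholdBand(t, 0.0))
        assert len(distinct) == c


class TestWasserstein:
    def test_self_distance_zero(self, rng):
        d = random_diagram(rng, 5)
        assert wasserstein_distance(d, d) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_to_empty(self):
        d = PersistenceDiagram([0.0], [0.4], [0])
        empty = PersistenceDiagram([], [], [])
        assert wasserstein_distance(d, empty, p=1) == pytest.approx(0.2)

    def test_order_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            wasserstein_distance(random_diagram(rng, 2), random_diagram(rng, 2), p=0.5)

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            na, nb = rng.integers(0, 5, 2)
            a, b = random_diagram(rng, na).points(0), random_diagram(rng, nb).points(0)
            for p in (1.0, 2.0):
                assert wasserstein_distance(a, b, p=p) == pytest.approx(
                    brute_force_wasserstein(a, b, p), abs=1e-9
                )

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(100):
            a, b, c = (random_diagram(rng, rng.integers(0, 6)) for _ in range(3))
            dab = wasserstein_distance(a, b)
            dba = wasserstein_distance(b, a)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= wasserstein_distance(a, c) + wasserstein_distance(c, b) + 1e-9

    def test_continuous_in_p_smoke(self, rng):
        a, b = random_diagram(rng, 4), random_diagram(rng, 3)
        vals = [wasserstein_distance(a, b, p=p) for p in np.linspace(1, 3, 9)]
        assert np.all(np.abs(np.diff(vals)) < 0.5)


class TestDistanceFromDiagonal:
    def test_empty_diagram_zero(self):
        assert distance_from_diagonal(PersistenceDiagram([], [], [])) == 0.0

    def test_closed_form_example(self):
        d = PersistenceDiagram([0.1, 0.2], [0.5, 0.4], [0, 0])
        assert distance_from_diagonal(d, p=1) == pytest.approx(0.3)

    def test_agrees_with_wasserstein_to_empty(self, rng):
        empty = PersistenceDiagram([], [], [])
        for _ in range(100):
            d = random_diagram(rng, rng.integers(0, 7))
            for p in (1.0, 2.0):
                assert distance_from_diagonal(d, p=p) == pytest.approx(
                    wasserstein_distance(d, empty, p=p), abs=1e-9
                )

    def test_additive_over_disjoint_union_p1(self, rng):
        d1, d2 = random_diagram(rng, 4), random_diagram(rng, 3)
        union = PersistenceDiagram(
            np.concatenate([d1.births, d2.births]),
            np.concatenate([d1.deaths, d2.deaths]),
            np.concatenate([d1.dims, d2.dims]),
        )
        assert distance_from_diagonal(union, p=1) == pytest.approx(
            distance_from_diagonal(d1, p=1) + distance_from_diagonal(d2, p=1)
        )


class TestSilhouette:
    def test_single_point_triangle(self):
        d = PersistenceDiagram([0.0], [1.0], [0])
        s = silhouette(d, dim=0, grid_size=1001)
        assert s.max() == pytest.approx(0.5, abs=1e-3)
        assert s.grid[np.argmax(s.values)] == pytest.approx(0.5, abs=1e-3)

    def test_duplicate_points_normalize_out(self):
        one = silhouette(PersistenceDiagram([0.1], [0.7], [0]), dim=0)
        two = silhouette(PersistenceDiagram([0.1, 0.1], [0.7, 0.7], [0, 0]), dim=0)
        assert np.allclose(one.values, two.values)

    def test_bounded_by_half_max_persistence(self, rng):
        for _ in range(20):
            d = random_diagram(rng, rng.integers(1, 8))
            s = silhouette(d, dim=0, power=rng.uniform(0, 3))
            assert s.max() <= d.persistence(0).max() / 2 + 1e-12

    def test_empty_diagram_zero_function(self):
        s = silhouette(PersistenceDiagram([], [], []), dim=1)
        assert not s.values.any()


class TestFractalDimension:
    def test_line_segment_near_one(self):
        mask = generate_phantom("line_segment", 128) > 0.5
        assert fractal_dimension(mask) == pytest.approx(1.0, abs=0.1)

    def test_ring_between_curve_and_plane(self):
        mask = generate_phantom("ring", 128) > 0.5
        assert 1.0 < fractal_dimension(mask) < 2.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.zeros((64, 64), bool))
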