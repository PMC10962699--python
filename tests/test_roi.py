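"""ROI definition (adaptive thresholds, clustering) and univariate statistics."""

import numpy as np
import pandas as pd
import pytest

from rsakit import (
    BetaSet,
    ResponseMatrix,
    ROIMask,
    StatMap,
    cluster_components,
    define_roi,
    group_condition_test,
    rating_response_correlation,
    roi_mean_responses,
    top_n_voxels,
)


def statmap_from_p(p, stat=None):
    p = np.asarray(p, dtype=float)
    if stat is None:
        stat = 1.0 - p
    return StatMap(np.asarray(stat, dtype=float), p)


def flood_fill_components(binary):
    """Oracle: breadth-first flood fill under 18-connectivity."""
    binary = np.asarray(binary).astype(bool)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) <= 2
    ]
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < binary.shape[0]
                    and 0 <= ny < binary.shape[1]
                    and 0 <= nz < binary.shape[2]
                    and binary[nx, ny, nz]
                    and not labels[nx, ny, nz]
                ):
                    labels[nx, ny, nz] = current
                    stack.append((nx, ny, nz))
    return labels


class TestClusterComponents:
    def test_solid_block(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[1:4, 1:4, 1:4] = True
        _, sizes = cluster_components(m)
        assert list(sizes) == [27]

    def test_corner_contact_splits(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, 0] = True
        m[1, 1, 1] = True  # shares only a corner
        _, sizes = cluster_components(m)
        assert len(sizes) == 2

    def test_edge_contact_joins(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, 0] = True
        m[1, 1, 0] = True  # shares an edge
        _, sizes = cluster_components(m)
        assert list(sizes) == [2]

    def test_face_contact_joins(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, 0] = True
        m[1, 0, 0] = True
        _, sizes = cluster_components(m)
        assert list(sizes) == [2]

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            m = rng.random((8, 8, 8)) < 0.3
            labels, sizes = cluster_components(m)
            oracle = flood_fill_components(m)
            assert labels.max() == oracle.max()
            # same partition: label images agree up to relabeling
            for k in range(1, labels.max() + 1):
                ours = labels == k
                theirs = oracle == oracle[ours][0] if ours.any() else ours
                assert np.array_equal(ours, theirs)


class TestDefineROI:
    def test_first_threshold_succeeds(self):
        p = np.ones((10, 10, 10))
        p[0:2, 0:5, 0:5] = 0.0005  # 50 contiguous voxels
        mask = ROIMask(np.ones((10, 10, 10), dtype=bool))
        roi = define_roi(statmap_from_p(p), mask)
        assert roi is not None
        assert roi.threshold == 0.001
        assert roi.n_voxels == 50

    def test_fallback_to_looser_threshold(self):
        p = np.ones((10, 10, 10))
        # 45-voxel bar significant at 0.005; only 30 of them at 0.001
        p[0, 0:5, 0:9] = 0.002
        p[0, 0:5, 0:6] = 0.0005
        mask = ROIMask(np.ones((10, 10, 10), dtype=bool))
        roi = define_roi(statmap_from_p(p), mask)
        assert roi is not None
        assert roi.threshold == 0.005
        assert roi.n_voxels == 45

    def test_nothing_survives(self):
        p = np.ones((6, 6, 6))
        mask = ROIMask(np.ones((6, 6, 6), dtype=bool))
        assert define_roi(statmap_from_p(p), mask) is None

    def test_small_cluster_dropped(self):
        p = np.ones((10, 10, 10))
        p[0, 0, 0:5] = 0.0005  # 5 voxels, below min_cluster at every threshold
        mask = ROIMask(np.ones((10, 10, 10), dtype=bool))
        assert define_roi(statmap_from_p(p), mask) is None

    def test_mask_restricts(self):
        p = np.ones((10, 10, 10))
        p[0:2, 0:5, 0:5] = 0.0005
        mask = ROIMask(np.zeros((10, 10, 10), dtype=bool))
        assert define_roi(statmap_from_p(p), mask) is None

    def test_monotone_in_min_cluster(self, rng):
        p = rng.random((12, 12, 12)) ** 3
        mask = ROIMask(np.ones((12, 12, 12), dtype=bool))
        sm = statmap_from_p(p)
        for mc_small, mc_large in [(5, 20), (10, 40)]:
            small = define_roi(sm, mask, min_cluster=mc_small)
            large = define_roi(sm, mask, min_cluster=mc_large)
            if large is not None and small is not None:
                if small.threshold == large.threshold:
                    assert large.n_voxels <= small.n_voxels

    def test_grid_mismatch_rejected(self):
        p = np.ones((4, 4, 4))
        mask = ROIMask(np.ones((5, 5, 5), dtype=bool))
        with pytest.raises(ValueError):
            define_roi(statmap_from_p(p), mask)


class TestTopN:
    def test_whole_mask(self, rng):
        stat = rng.standard_normal((4, 4, 4))
        mask = ROIMask(rng.random((4, 4, 4)) < 0.5)
        sm = StatMap(stat, np.full((4, 4, 4), 0.5))
        out = top_n_voxels(sm, mask, mask.n_voxels)
        assert np.array_equal(out.mask, mask.mask)

    def test_argmax_voxel(self, rng):
        stat = rng.standard_normal((4, 4, 4))
        mask = ROIMask(np.ones((4, 4, 4), dtype=bool))
        sm = StatMap(stat, np.full((4, 4, 4), 0.5))
        out = top_n_voxels(sm, mask, 1)
        assert out.mask.sum() == 1
        assert stat[out.mask][0] == stat.max()

    def test_tie_break_deterministic(self):
        stat = np.zeros((3, 3, 3))  # all tied
        mask = ROIMask(np.ones((3, 3, 3), dtype=bool))
        sm = StatMap(stat, np.full((3, 3, 3), 0.5))
        results = [top_n_voxels(sm, mask, 5).indices() for _ in range(3)]
        for r in results[1:]:
            assert np.array_equal(r, results[0])
        # ties broken by linear voxel index: lowest indices win
        assert np.array_equal(results[0], np.arange(5))

    def test_oversized_request_rejected(self):
        mask = ROIMask(np.ones((2, 2, 2), dtype=bool))
        sm = StatMap(np.zeros((2, 2, 2)), np.full((2, 2, 2), 0.5))
        with pytest.raises(ValueError):
            top_n_voxels(sm, mask, 9)


def make_beta_set(design, rng, n_participants=3, n_voxels=6, values=None):
    ids = design.ids
    patterns = {}
    for p in range(n_participants):
        vals = (
            values
            if values is not None
            else rng.standard_normal((len(ids), n_voxels))
        )
        patterns[f"p{p}"] = ResponseMatrix(vals, ids, participant_id=f"p{p}")
    return BetaSet(patterns, design)


class TestROIMeans:
    def test_constant_beta(self, design, rng):
        betas = make_beta_set(design, rng, values=np.full((48, 6), 2.5))
        out = roi_mean_responses(betas, grouping="object_type")
        assert np.allclose(out.to_numpy(), 2.5)

    def test_two_voxel_mean(self, design):
        vals = np.column_stack([np.ones(48), 3 * np.ones(48)])
        betas = BetaSet(
            {"p0": ResponseMatrix(vals, design.ids)}, design
        )
        out = roi_mean_responses(betas, grouping="exemplar")
        assert np.allclose(out.to_numpy(), 2.0)

    def test_matches_nested_loop_oracle(self, design, rng):
        betas = make_beta_set(design, rng, n_participants=2)
        out = roi_mean_responses(betas, grouping="object_type")
        for pid, pm in betas.patterns.items():
            for otype in out.columns:
                rows = [
                    i
                    for i, s in enumerate(design)
                    if s.object_type == otype
                ]
                expected = np.mean([pm.values[i].mean() for i in rows])
                assert out.loc[pid, otype] == pytest.approx(expected)

    def test_voxel_order_invariance(self, design, rng):
        vals = rng.standard_normal((48, 8))
        a = BetaSet({"p0": ResponseMatrix(vals, design.ids)}, design)
        b = BetaSet({"p0": ResponseMatrix(vals[:, ::-1], design.ids)}, design)
        pd.testing.assert_frame_equal(
            roi_mean_responses(a, "shape_type"), roi_mean_responses(b, "shape_type")
        )


class TestGroupConditionTest:
    def test_identical_conditions(self):
        means = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]})
        t, df, p = group_condition_test(means, "x", "y")
        assert t == 0.0 and p == 1.0
        assert df == 2

    def test_consistent_difference_detected(self, rng):
        n = 12
        base = rng.standard_normal(n)
        means = pd.DataFrame(
            {"x": base + 1.0 + 0.1 * rng.standard_normal(n), "y": base}
        )
        t, df, p = group_condition_test(means, "x", "y")
        assert t > 0 and p < 0.001
        assert df == n - 1

    def test_zero_variance_nonzero_diff_flagged(self):
        means = pd.DataFrame({"x": [2.0, 3.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            group_condition_test(means, "x", "y")


class TestRatingResponseCorrelation:
    def test_responses_equal_ratings(self, design, rng):
        ratings = pd.Series(
            np.linspace(1, 7, 48), index=list(design.ids)
        )
        vals = np.tile(ratings.to_numpy()[:, None], (1, 5))
        betas = BetaSet(
            {f"p{i}": ResponseMatrix(vals, design.ids) for i in range(3)}, design
        )
        rs, (t, df, p) = rating_response_correlation(ratings, betas)
        assert np.allclose(rs.to_numpy(), 1.0)
        assert p < 0.05

    def test_negated_responses(self, design):
        ratings = pd.Series(np.linspace(1, 7, 48), index=list(design.ids))
        vals = np.tile(-ratings.to_numpy()[:, None], (1, 5))
        betas = BetaSet({"p0": ResponseMatrix(vals, design.ids), "p1": ResponseMatrix(vals, design.ids)}, design)
        rs, _ = rating_response_correlation(ratings, betas)
        assert np.allclose(rs.to_numpy(), -1.0)

    def test_independent_responses_small_t(self, design, rng):
        ratings = pd.Series(
            rng.integers(1, 8, 48).astype(float), index=list(design.ids)
        )
        betas = make_beta_set(design, rng, n_participants=16, n_voxels=10)
        _, (t, df, p) = rating_response_correlation(ratings, betas)
        assert abs(t) < 3.0
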