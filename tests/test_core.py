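"""Unit and property tests for the core clustering pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focal3d import (
    ClusteringParams,
    LocalizationTable,
    build_density_map,
    classify_voxels,
    enhance_density_map,
    extract_clusters,
    focal3d,
)
from focal3d.core import EnhancedDensityMap, VoxelGrid

from oracles import (
    brute_bin_counts,
    brute_classify,
    brute_components,
    brute_enhance,
    brute_pipeline,
)


def _edm_from_counts(counts):
    """Wrap a raw count grid as a grid + enhanced map pair."""
    counts = np.asarray(counts)
    grid = VoxelGrid(
        origin=np.zeros(3),
        delta=1.0,
        dims=counts.shape,
        counts=counts,
        point_index=np.empty((0, 3), dtype=np.int64),
    )
    return enhance_density_map(grid)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


class TestBinning:
    def test_empty_table(self):
        grid = build_density_map(LocalizationTable(np.empty((0, 3))), delta=10.0)
        assert grid.counts.sum() == 0

    def test_single_point(self):
        t = LocalizationTable(np.array([[5.0, 5.0, 5.0]]))
        grid = build_density_map(t, delta=10.0, bounds=([0, 0, 0], [10, 10, 10]))
        assert grid.counts[0, 0, 0] == 1
        assert grid.counts.sum() == 1

    def test_uniform_points_match_brute_force(self, rng):
        xyz = rng.uniform(0, 100, size=(1000, 3))
        grid = build_density_map(LocalizationTable(xyz), delta=10.0)
        expected = brute_bin_counts(xyz, grid.origin, grid.delta, grid.dims)
        assert grid.counts.sum() == 1000
        np.testing.assert_array_equal(grid.counts, expected)

    def test_point_on_upper_boundary_falls_in_last_voxel(self):
        t = LocalizationTable(np.array([[0.0, 0.0, 0.0], [100.0, 100.0, 100.0]]))
        grid = build_density_map(t, delta=10.0)
        assert grid.dims == (10, 10, 10)
        assert grid.counts[9, 9, 9] == 1
        assert grid.counts.sum() == 2

    def test_explicit_bounds_drop_outside_points(self):
        xyz = np.array([[5.0, 5.0, 5.0], [50.0, 5.0, 5.0]])
        grid = build_density_map(
            LocalizationTable(xyz), delta=10.0, bounds=([0, 0, 0], [10, 10, 10])
        )
        assert grid.counts.sum() == 1
        assert not grid.in_bounds[1]

    def test_non_positive_delta_rejected(self):
        with pytest.raises(ValueError):
            build_density_map(LocalizationTable(np.zeros((1, 3))), delta=0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(1, 200),
        delta=st.floats(1.0, 50.0),
    )
    def test_count_conservation(self, seed, n, delta):
        """Sum of voxel counts equals the number of binned localizations."""
        xyz = np.random.default_rng(seed).uniform(-50, 150, size=(n, 3))
        grid = build_density_map(LocalizationTable(xyz), delta=delta)
        assert grid.counts.sum() == n
        assert grid.in_bounds.all()


# ---------------------------------------------------------------------------
# Enhanced density map
# ---------------------------------------------------------------------------


class TestEnhancement:
    def test_isolated_voxel(self):
        counts = np.zeros((5, 5, 5), dtype=int)
        counts[2, 2, 2] = 7
        edm = _edm_from_counts(counts)
        assert edm.enhanced[2, 2, 2] == 7

    def test_uniform_grid_interior_is_27(self):
        edm = _edm_from_counts(np.ones((5, 5, 5), dtype=int))
        assert edm.enhanced[2, 2, 2] == 27
        assert edm.enhanced[0, 0, 0] == 8  # corner sees only 8 in-bounds voxels

    def test_random_grid_matches_triple_loop(self, rng):
        counts = rng.integers(0, 5, size=(20, 20, 20))
        edm = _edm_from_counts(counts)
        expected = brute_enhance(counts)
        nz = counts > 0
        np.testing.assert_array_equal(edm.enhanced[nz], expected[nz])

    def test_empty_voxels_are_ineligible(self, rng):
        counts = rng.integers(0, 3, size=(6, 6, 6))
        edm = _edm_from_counts(counts)
        assert not edm.eligible[counts == 0].any()

    def test_strict_edges_excludes_outer_layer(self):
        counts = np.ones((5, 5, 5), dtype=int)
        grid = VoxelGrid(
            origin=np.zeros(3),
            delta=1.0,
            dims=(5, 5, 5),
            counts=counts,
            point_index=np.empty((0, 3), dtype=np.int64),
        )
        edm = enhance_density_map(grid, strict_edges=True)
        assert not edm.eligible[0].any() and not edm.eligible[-1].any()
        assert edm.eligible[2, 2, 2]
        # strict mode affects core eligibility only; counts untouched
        assert (edm.grid.counts == 1).all()


# ---------------------------------------------------------------------------
# Core / border classification
# ---------------------------------------------------------------------------


class TestClassification:
    def test_subthreshold_gives_empty_masks(self):
        counts = np.ones((4, 4, 4), dtype=int)
        core, border = classify_voxels(_edm_from_counts(counts), min_l=100)
        assert not core.any() and not border.any()

    def test_border_is_face_adjacent_only(self):
        # centre voxel count 100, its 6 face neighbours count 1 each:
        # enhanced(centre) = 106, enhanced(face voxel) = 100 + 1 + 4 = 105,
        # so at min_l = 106 only the centre is core, the 6 occupied face
        # neighbours are border, and the 20 (empty) diagonal neighbours are not
        counts = np.zeros((5, 5, 5), dtype=int)
        counts[2, 2, 2] = 100
        for off in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            counts[2 + off[0], 2 + off[1], 2 + off[2]] = 1
        core, border = classify_voxels(_edm_from_counts(counts), min_l=106)
        assert core.sum() == 1 and core[2, 2, 2]
        assert border.sum() == 6
        assert border[1, 2, 2] and border[3, 2, 2]
        assert not border[1, 1, 2]  # diagonal position is not border

    @pytest.mark.parametrize("min_l", [1, 5, 20, 60])
    def test_random_grid_matches_per_voxel_oracle(self, rng, min_l):
        counts = rng.integers(0, 4, size=(12, 12, 12))
        edm = _edm_from_counts(counts)
        core, border = classify_voxels(edm, min_l)
        exp_core, exp_border = brute_classify(counts, brute_enhance(counts), min_l)
        np.testing.assert_array_equal(core, exp_core)
        np.testing.assert_array_equal(border, exp_border)

    def test_inclusive_flag_pins_threshold_comparison(self):
        counts = np.zeros((3, 3, 3), dtype=int)
        counts[1, 1, 1] = 14
        edm = _edm_from_counts(counts)
        core_inc, _ = classify_voxels(edm, 14, inclusive=True)
        core_exc, _ = classify_voxels(edm, 14, inclusive=False)
        assert core_inc[1, 1, 1] and not core_exc[1, 1, 1]

    def test_min_l_monotonicity_core_subset(self, rng):
        """Raising min_l can only shrink the core voxel set."""
        counts = rng.integers(0, 4, size=(15, 15, 15))
        edm = _edm_from_counts(counts)
        for min_l in range(1, 30):
            lo, _ = classify_voxels(edm, min_l)
            hi, _ = classify_voxels(edm, min_l + 1)
            assert not (hi & ~lo).any()


# ---------------------------------------------------------------------------
# Cluster extraction
# ---------------------------------------------------------------------------


class TestExtraction:
    def test_no_core_no_clusters(self):
        empty = np.zeros((4, 4, 4), dtype=bool)
        border = np.ones((4, 4, 4), dtype=bool)
        _, clusters = extract_clusters(empty, border, min_c=1)
        assert clusters == []

    def test_min_c_threshold_boundary(self):
        core = np.zeros((5, 5, 5), dtype=bool)
        border = np.zeros((5, 5, 5), dtype=bool)
        core[2, 2, 2] = True
        border[1, 2, 2] = border[3, 2, 2] = border[2, 1, 2] = True
        _, c4 = extract_clusters(core, border, min_c=4)
        _, c5 = extract_clusters(core, border, min_c=5)
        assert len(c4) == 1
        assert c4[0]["core"].shape[0] + c4[0]["border"].shape[0] == 4
        assert len(c5) == 0

    def test_components_match_bfs_oracle(self, rng):
        core = rng.uniform(size=(15, 15, 15)) < 0.3
        border = np.zeros_like(core)
        labels, clusters = extract_clusters(core, border, min_c=1)
        exp = brute_components(core)
        # same partition: bijection between label sets
        assert len(clusters) == exp.max()
        for k in range(1, exp.max() + 1):
            mine = labels[exp == k]
            assert (mine == mine[0]).all() and mine[0] > 0

    def test_border_tiebreak_is_deterministic(self):
        # one border voxel equidistant between two single-voxel components:
        # one adjacent face each -> goes to the smaller canonical index
        core = np.zeros((5, 1, 1), dtype=bool)
        core[1, 0, 0] = core[3, 0, 0] = True
        border = np.zeros_like(core)
        border[2, 0, 0] = True
        labels, clusters = extract_clusters(core, border, min_c=1)
        assert len(clusters) == 2
        assert labels[2, 0, 0] == labels[1, 0, 0] == 1

    def test_masks_must_be_disjoint(self):
        m = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(ValueError):
            extract_clusters(m, m, min_c=1)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


class TestFocal3d:
    def test_empty_table(self):
        res = focal3d(
            LocalizationTable(np.empty((0, 3))), ClusteringParams(10.0, 1, 1)
        )
        assert res.n_clusters == 0 and res.labels.size == 0

    def test_two_blobs_recovered(self, two_blob_table):
        res = focal3d(two_blob_table, ClusteringParams(40.0, 5, 2))
        assert res.n_clusters == 2
        labels = res.labels
        first, second = labels[:200], labels[200:]
        # >= 99% of each blob's points carry that blob's (majority) label
        assert (first == np.bincount(first[first >= 0]).argmax()).mean() >= 0.99
        assert (second == np.bincount(second[second >= 0]).argmax()).mean() >= 0.99

    @pytest.mark.parametrize("min_l,min_c", [(1, 1), (3, 2), (6, 4), (12, 3)])
    def test_pipeline_matches_brute_force(self, rng, min_l, min_c):
        """Voxel-for-voxel equivalence with an independent implementation."""
        xyz = rng.uniform(0, 15, size=(350, 3))
        table = LocalizationTable(xyz)
        res = focal3d(table, ClusteringParams(1.0, min_l, min_c))
        grid = build_density_map(table, 1.0)
        expected_vox = brute_pipeline(grid.counts, min_l, min_c)
        # same clusters, same canonical order
        assert len(res.clusters) == expected_vox.max()
        for k, cl in enumerate(res.clusters):
            vox = np.vstack([cl.core_voxels, cl.border_voxels])
            assert (expected_vox[tuple(vox.T)] == k + 1).all()
        # localization labels agree with the oracle's voxel labels
        pt_expected = expected_vox[tuple(grid.point_index.T)] - 1
        np.testing.assert_array_equal(res.labels, pt_expected)

    def test_cluster_size_invariant(self, two_blob_table):
        res = focal3d(two_blob_table, ClusteringParams(40.0, 5, 2))
        for k, cl in enumerate(res.clusters):
            assert cl.n_voxels >= 2
            assert cl.n_localizations == (res.labels == k).sum()

    def test_permutation_invariance(self, rng, small_sim):
        table = small_sim.table
        params = ClusteringParams(30.0, 5, 5)
        base = focal3d(table, params)
        perm = rng.permutation(table.n_l)
        shuffled = focal3d(LocalizationTable(table.xyz[perm]), params)
        np.testing.assert_array_equal(shuffled.labels, base.labels[perm])

    def test_translation_invariance(self, small_sim):
        table = small_sim.table
        params = ClusteringParams(30.0, 5, 5)
        base = focal3d(table, params)
        shifted = focal3d(
            LocalizationTable(table.xyz + np.array([90.0, -60.0, 30.0])), params
        )
        np.testing.assert_array_equal(shifted.labels, base.labels)

    def test_min_c_monotonicity(self, small_sim):
        """Cluster count is non-increasing in min_c (pure size filter)."""
        counts = [
            focal3d(small_sim.table, ClusteringParams(30.0, 5, mc)).n_clusters
            for mc in range(1, 25)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_determinism(self, small_sim):
        params = ClusteringParams(30.0, 5, 5)
        a = focal3d(small_sim.table, params)
        b = focal3d(small_sim.table, params)
        np.testing.assert_array_equal(a.labels, b.labels)
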