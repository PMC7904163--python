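"""18-connected labeling, solidity, filters and ranking, checked against
brute-force oracles (union-find labeling; half-space point-in-hull tests)."""

import itertools

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from qmriclust import (
    Cluster,
    ClusterSet,
    cluster_report,
    cluster_solidity,
    cross_metric_dice,
    hull_voxel_count,
    label_clusters,
    rank_clusters,
    roi_overlap,
    size_filter,
    solidity_filter,
)

from conftest import mask_of

# the 18-neighborhood: face (one nonzero offset) and edge (two) neighbors
OFFSETS_18 = [o for o in itertools.product((-1, 0, 1), repeat=3)
              if 0 < sum(abs(v) for v in o) <= 2]


def union_find_label(volume):
    """Oracle: connected components via explicit union-find over offsets."""
    parent = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    coords = [tuple(c) for c in np.argwhere(volume)]
    for c in coords:
        parent[c] = c
    cs = set(coords)
    for c in coords:
        for o in OFFSETS_18:
            n = (c[0] + o[0], c[1] + o[1], c[2] + o[2])
            if n in cs:
                union(c, n)
    groups = {}
    for c in coords:
        groups.setdefault(find(c), set()).add(c)
    return {frozenset(g) for g in groups.values()}


def brute_force_hull_count(voxels):
    """Oracle: count bounding-box voxel centers satisfying every hull facet
    inequality (full-dimensional clusters only)."""
    pts = np.asarray(voxels, float)
    hull = ConvexHull(pts)
    lo, hi = pts.min(0).astype(int), pts.max(0).astype(int)
    count = 0
    for p in itertools.product(*[range(a, b + 1) for a, b in zip(lo, hi)]):
        if np.all(hull.equations[:, :3] @ np.asarray(p, float)
                  + hull.equations[:, 3] <= 1e-9):
            count += 1
    return count


def _cluster(voxels):
    return Cluster(label=1, voxels=np.asarray(voxels, int))


def _set(clusters, shape=(20, 20, 20)):
    return ClusterSet(list(clusters), shape)


class TestLabelClusters:
    def test_isolated_voxel(self):
        vol = np.zeros((5, 5, 5), bool)
        vol[2, 2, 2] = True
        cs = label_clusters(vol)
        assert len(cs) == 1 and cs.clusters[0].size == 1

    def test_corner_contact_does_not_connect(self):
        vol = np.zeros((4, 4, 4), bool)
        vol[1, 1, 1] = vol[2, 2, 2] = True
        assert len(label_clusters(vol)) == 2

    def test_edge_contact_connects(self):
        vol = np.zeros((4, 4, 4), bool)
        vol[1, 1, 1] = vol[2, 2, 1] = True
        cs = label_clusters(vol)
        assert len(cs) == 1 and cs.clusters[0].size == 2

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            label_clusters(np.full((3, 3, 3), 0.5))

    @pytest.mark.parametrize("density", [0.05, 0.15, 0.3, 0.5])
    def test_matches_union_find_oracle(self, rng, density):
        vol = rng.random((20, 20, 20)) < density
        ours = {frozenset(map(tuple, c.voxels)) for c in label_clusters(vol)}
        assert ours == union_find_label(vol)

    def test_partition_covers_input(self, rng):
        vol = rng.random((15, 15, 15)) < 0.2
        cs = label_clusters(vol)
        seen = np.zeros(vol.shape, bool)
        for c in cs.clusters:
            assert not seen[tuple(c.voxels.T)].any()  # pairwise disjoint
            seen[tuple(c.voxels.T)] = True
        np.testing.assert_array_equal(seen, vol)


class TestSolidity:
    def test_full_cube_is_solid(self):
        cube = list(itertools.product(range(3), repeat=3))
        assert cluster_solidity(_cluster(cube)) == 1.0

    def test_hollow_shell(self):
        shell = [v for v in itertools.product(range(3), repeat=3) if v != (1, 1, 1)]
        c = _cluster(shell)
        assert c.solidity == pytest.approx(26 / 27)

    def test_planar_v_shape_has_low_solidity(self):
        # two 10-voxel arms at a right angle in the z=0 plane: the in-plane
        # hull fills the triangle between them
        arm1 = [(i, 0, 0) for i in range(10)]
        arm2 = [(0, j, 0) for j in range(1, 10)]
        c = _cluster(arm1 + arm2)
        triangle = sum(1 for i in range(10) for j in range(10) if i + j <= 9)
        assert c.hull_volume is None
        assert c.solidity == pytest.approx(19 / triangle)
        assert c.solidity < 0.5

    def test_single_voxel_and_line(self):
        assert hull_voxel_count(np.array([[3, 4, 5]])) == 1
        # a gappy straight line: hull includes the skipped centers
        line = _cluster([(0, 0, 0), (2, 0, 0), (6, 0, 0)])
        assert line.hull_volume is None or True
        assert hull_voxel_count(line.voxels) == 7

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_solidity(_cluster(np.empty((0, 3))))

    def test_matches_brute_force_oracle(self, rng):
        # random full-dimensional blobs up to 500 voxels
        for _ in range(15):
            n = rng.integers(4, 60)
            vox = np.unique(rng.integers(0, 8, size=(n, 3)), axis=0)
            if np.linalg.matrix_rank(vox - vox[0]) < 3:
                continue
            assert hull_voxel_count(vox) == brute_force_hull_count(vox)

    def test_large_cluster_matches_oracle(self, rng):
        vox = np.argwhere(rng.random((10, 10, 10)) < 0.45)
        assert len(vox) <= 500
        assert hull_voxel_count(vox) == brute_force_hull_count(vox)


class TestFilters:
    def _cube(self, origin, edge):
        return _cluster([(origin[0] + i, origin[1] + j, origin[2] + k)
                         for i in range(edge) for j in range(edge) for k in range(edge)])

    def test_size_filter_boundary(self):
        cube27 = self._cube((0, 0, 0), 3)
        cs = size_filter(_set([cube27]), 27)
        assert len(cs) == 1  # the 3x3x3 cube survives
        short = _cluster(cube27.voxels[:26])
        assert len(size_filter(_set([short]), 27)) == 0

    def test_size_filter_keeps_large(self):
        sizes = {10: self._cube((0, 0, 0), 2), 27: self._cube((5, 5, 5), 3),
                 343: self._cube((10, 10, 10), 7)}
        sizes[10].voxels = sizes[10].voxels[:8]
        cs = size_filter(_set(sizes.values()), 27)
        assert sorted(c.size for c in cs.clusters) == [27, 343]

    def test_solidity_filter(self):
        solid = self._cube((0, 0, 0), 3)
        # sparse filament along three tetrahedron edges: 10 voxels whose
        # hull fills the 220-point tetrahedron -> solidity ~0.045
        filament = _cluster([(i, 0, 0) for i in (0, 3, 6, 9)]
                            + [(0, j, 0) for j in (3, 6, 9)]
                            + [(0, 0, k) for k in (3, 6, 9)])
        assert filament.solidity == pytest.approx(10 / 220)
        cs = solidity_filter(_set([solid, filament]), 0.1)
        assert [c.size for c in cs.clusters] == [27]

    def test_zero_threshold_is_identity(self):
        clusters = [self._cube((0, 0, 0), 2), self._cube((5, 5, 5), 3)]
        cs = solidity_filter(_set(clusters), 0.0)
        assert len(cs) == len(clusters)

    def test_filters_only_remove_never_merge(self, rng):
        vol = rng.random((20, 20, 20)) < 0.25
        cs = label_clusters(vol)
        inputs = {frozenset(map(tuple, c.voxels)) for c in cs.clusters}
        out = solidity_filter(size_filter(cs, 5), 0.2)
        for c in out.clusters:
            assert frozenset(map(tuple, c.voxels)) in inputs

    def test_filter_order_independent(self, rng):
        vol = rng.random((20, 20, 20)) < 0.25
        cs = label_clusters(vol)
        a = solidity_filter(size_filter(cs, 10), 0.3)
        b = size_filter(solidity_filter(cs, 0.3), 10)
        assert [c.label for c in a.clusters] == [c.label for c in b.clusters]


class TestRanking:
    def _of_sizes(self, *sizes):
        clusters = []
        for i, s in enumerate(sizes):
            vox = [(10 * i, j, 0) for j in range(s)]
            clusters.append(Cluster(label=i + 1, voxels=np.asarray(vox)))
        return _set(clusters, shape=(100, 800, 10))

    def test_sorted_biggest_first(self):
        ranked = rank_clusters(self._of_sizes(100, 700, 50))
        assert [c.size for c in ranked.clusters] == [700, 100, 50]
        assert [c.rank for c in ranked.clusters] == [1, 2, 3]

    def test_ties_broken_by_centroid(self):
        ranked = rank_clusters(self._of_sizes(5, 5))
        assert [c.label for c in ranked.clusters] == [1, 2]  # lower centroid first

    def test_empty_set(self):
        assert len(rank_clusters(_set([]))) == 0


class TestOverlapAndReport:
    def test_roi_overlap_fractions(self):
        inside = _cluster([(1, 1, 1), (1, 1, 2)])
        outside = _cluster([(15, 15, 15)])
        roi = np.zeros((20, 20, 20), bool)
        roi[:5, :5, :5] = True
        table = roi_overlap(rank_clusters(_set([inside, outside])), mask_of(roi))
        by_size = table.set_index("size_voxels")["frac_in_roi"]
        assert by_size[2] == 1.0 and by_size[1] == 0.0

    def test_cross_metric_dice(self):
        roi = mask_of(np.ones((20, 20, 20)))
        a = _set([_cluster([(1, 1, 1), (1, 1, 2)])])
        b = _set([_cluster([(1, 1, 1), (1, 1, 2)])])
        disjoint = _set([_cluster([(9, 9, 9)])])
        assert cross_metric_dice(a, b, roi) == 1.0
        assert cross_metric_dice(a, disjoint, roi) == 0.0

    def test_report_counts_and_columns(self, rng):
        vol = np.zeros((20, 20, 20), bool)
        vol[1:4, 1:4, 1:4] = True          # 27-voxel cube, survives
        vol[10, 10, 10] = True             # singleton, removed
        vol[15, 1, 1] = vol[15, 1, 2] = True  # pair, removed
        cs = label_clusters(vol)
        assert len(cs) == 3
        survivors = rank_clusters(solidity_filter(size_filter(cs), 0.1))
        assert len(survivors) == 1
        report = cluster_report(survivors)
        assert "atlas_labels" not in report.columns
        assert report.loc[0, "size_voxels"] == 27
        atlas = np.zeros((20, 20, 20), np.int32)
        atlas[1:4, 1:4, 1:4] = 5
        report = cluster_report(survivors, atlas=atlas, atlas_labels={5: "SN"})
        assert report.loc[0, "atlas_labels"] == "SN"
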