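"""Cluster extraction and geometric filtering of H1 maps.

Voxels rejecting the null are grouped into 18-connected components (face
and edge neighbors; corner-only contact does not connect), then filtered
by two per-cluster predicates:

- size >= 27 voxels (the 3x3x3 cube, the usual noise floor for segmented
  volumes);
- solidity >= 0.1, where solidity is the cluster's voxel count divided by
  the voxel count of its filled convex hull.  Sparse, filamentary clusters
  typical of tissue-interface misregistration have low solidity; compact
  blobs score near 1.

Surviving clusters are ranked from biggest to smallest.  Hull filling is
discrete: a voxel belongs to the hull when its center lies inside or on
the convex hull of the cluster's voxel centers, which keeps solidity a
ratio of commensurable counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .volumes import AnalysisMask
from .inference import H1Map

#: 18-connectivity structuring element: 6 face + 12 edge neighbors.
STRUCTURE_18 = ndimage.generate_binary_structure(3, 2)


@dataclass
class Cluster:
    """One connected component of an H1 map."""

    label: int
    voxels: np.ndarray  # (N, 3) int indices
    hull_volume: int | None = None
    rank: int | None = None

    @property
    def size(self) -> int:
        return self.voxels.shape[0]

    @property
    def centroid(self) -> tuple[float, float, float]:
        return tuple(self.voxels.mean(axis=0))

    @property
    def solidity(self) -> float:
        if self.hull_volume is None:
            self.hull_volume = hull_voxel_count(self.voxels)
        return self.size / self.hull_volume

    def to_mask(self, shape: tuple[int, ...]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[tuple(self.voxels.T)] = True
        return out


@dataclass
class ClusterSet:
    """Disjoint clusters extracted from one H1 map, with filter provenance."""

    clusters: list
    shape: tuple[int, ...]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    filters_applied: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def labels_volume(self) -> np.ndarray:
        """int32 volume with each voxel set to its cluster's rank (or label)."""
        out = np.zeros(self.shape, dtype=np.int32)
        for c in self.clusters:
            out[tuple(c.voxels.T)] = c.rank if c.rank is not None else c.label
        return out


def label_clusters(h1: H1Map | np.ndarray) -> ClusterSet:
    """Partition H1 voxels into maximal 18-connected components."""
    if isinstance(h1, H1Map):
        data, affine = h1.data, h1.affine
    else:
        data = np.asarray(h1)
        affine = np.eye(4)
        if not np.isin(data, (0, 1)).all():
            raise ValueError("cluster labeling expects a binary volume")
        data = data.astype(bool)
    labeled, n = ndimage.label(data, structure=STRUCTURE_18)
    clusters = []
    if n:
        # ndimage.find_objects keeps per-cluster work local to its bounding box
        for lab, slc in enumerate(ndimage.find_objects(labeled), start=1):
            idx = np.argwhere(labeled[slc] == lab)
            idx += [s.start for s in slc]
            clusters.append(Cluster(label=lab, voxels=idx))
    return ClusterSet(clusters, data.shape, affine, ["18-connected labeling"])


def _bbox_grid(pts: np.ndarray) -> np.ndarray:
    lo = pts.min(axis=0).astype(int)
    hi = pts.max(axis=0).astype(int)
    return np.stack(np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)],
                                indexing="ij"), axis=-1).reshape(-1, 3).astype(np.float64)


def hull_voxel_count(voxels: np.ndarray) -> int:
    """Voxels whose centers lie inside or on the convex hull of ``voxels``.

    Clusters whose centers span fewer than three dimensions — thin sheets
    and lines, the shape of tissue-interface misregistration residue — are
    filled within the affine subspace they span: the hull of a planar
    cluster is its filled polygon, of a collinear cluster the voxel centers
    on its segment.  A single voxel has hull volume 1.
    """
    pts = np.unique(np.asarray(voxels, dtype=np.float64), axis=0)
    if pts.shape[0] == 1:
        return 1
    centered = pts - pts.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-9)

    if rank == 1:
        direction = centered[np.abs(centered).sum(axis=1).argmax()]
        direction = direction / np.linalg.norm(direction)
        grid = _bbox_grid(pts)
        rel = grid - pts.mean(axis=0)
        t = rel @ direction
        perp = np.linalg.norm(rel - np.outer(t, direction), axis=1)
        on_line = (perp < 1e-9) & (t >= (centered @ direction).min() - 1e-9) \
            & (t <= (centered @ direction).max() + 1e-9)
        return int(on_line.sum())

    if rank == 2:
        # orthonormal in-plane basis from the two leading singular vectors
        _, _, vt = np.linalg.svd(centered, full_matrices=True)
        basis, normal = vt[:2], vt[2]
        grid = _bbox_grid(pts)
        rel = grid - pts.mean(axis=0)
        in_plane = np.abs(rel @ normal) < 1e-9
        candidates = rel[in_plane] @ basis.T
        pts2 = centered @ basis.T
        try:
            hull2 = ConvexHull(pts2)
            tri2 = Delaunay(pts2[hull2.vertices])
        except QhullError:
            return pts.shape[0]
        return int((tri2.find_simplex(candidates, tol=1e-9) >= 0).sum())

    try:
        # triangulating only the hull vertices keeps large clusters cheap
        hull = ConvexHull(pts)
        tri = Delaunay(pts[hull.vertices])
    except QhullError:
        return pts.shape[0]
    inside = tri.find_simplex(_bbox_grid(pts), tol=1e-9) >= 0
    return int(inside.sum())


def cluster_solidity(cluster: Cluster) -> float:
    """size / hull_volume, in (0, 1]."""
    if cluster.size == 0:
        raise ValueError("solidity of an empty cluster is undefined")
    return cluster.solidity


def size_filter(cs: ClusterSet, min_size: int = 27) -> ClusterSet:
    """Retain clusters with at least ``min_size`` voxels (inclusive: a
    3x3x3 cube of 27 voxels survives the default)."""
    kept = [c for c in cs.clusters if c.size >= min_size]
    return ClusterSet(kept, cs.shape, cs.affine,
                      cs.filters_applied + [f"size >= {min_size}"])


def solidity_filter(cs: ClusterSet, min_solidity: float = 0.1) -> ClusterSet:
    """Retain clusters with solidity >= ``min_solidity`` (inclusive)."""
    kept = [c for c in cs.clusters if c.solidity >= min_solidity]
    return ClusterSet(kept, cs.shape, cs.affine,
                      cs.filters_applied + [f"solidity >= {min_solidity}"])


def rank_clusters(cs: ClusterSet) -> ClusterSet:
    """Sort from biggest to smallest and assign ranks 1..K.

    Ties are broken by ascending centroid (z, y, x read as the first,
    second, third index) so the ordering is deterministic.
    """
    ordered = sorted(cs.clusters, key=lambda c: (-c.size, c.centroid))
    ranked = [replace(c, rank=i) for i, c in enumerate(ordered, start=1)]
    return ClusterSet(ranked, cs.shape, cs.affine, cs.filters_applied + ["ranked"])


def roi_overlap(cs: ClusterSet, roi: AnalysisMask) -> pd.DataFrame:
    """Per-cluster fraction of voxels inside the ROI."""
    if cs.shape != roi.shape:
        raise ValueError("cluster set and ROI are on different grids")
    rows = []
    for c in cs.clusters:
        inside = roi.data[tuple(c.voxels.T)].sum()
        rows.append({"rank": c.rank, "size_voxels": c.size,
                     "frac_in_roi": inside / c.size})
    return pd.DataFrame(rows, columns=["rank", "size_voxels", "frac_in_roi"])


def cross_metric_dice(a: ClusterSet, b: ClusterSet, roi: AnalysisMask) -> float:
    """Dice overlap of two cluster sets' voxel unions restricted to the ROI.

    Used to compare detections across metrics within a search region; 1.0
    for identical sets, 0.0 for disjoint ones.  Defined as 1.0 when both
    sets are empty inside the ROI (perfect agreement on absence).
    """
    ma = np.zeros(roi.shape, dtype=bool)
    mb = np.zeros(roi.shape, dtype=bool)
    for c in a.clusters:
        ma[tuple(c.voxels.T)] = True
    for c in b.clusters:
        mb[tuple(c.voxels.T)] = True
    ma &= roi.data
    mb &= roi.data
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def cluster_report(
    cs: ClusterSet,
    roi: AnalysisMask | None = None,
    atlas: np.ndarray | None = None,
    atlas_labels: dict | None = None,
) -> pd.DataFrame:
    """Tabulate per-cluster geometry: rank, size, solidity, centroid, ROI
    fraction, and (when an atlas volume is supplied) overlapping region
    names."""
    rows = []
    for c in cs.clusters:
        ci, cj, ck = c.centroid
        row = {
            "rank": c.rank,
            "size_voxels": c.size,
            "solidity": round(c.solidity, 4),
            "centroid_x": round(ci, 2),
            "centroid_y": round(cj, 2),
            "centroid_z": round(ck, 2),
        }
        if roi is not None:
            inside = roi.data[tuple(c.voxels.T)].sum()
            row["frac_in_roi"] = round(inside / c.size, 4)
        if atlas is not None:
            labs = np.unique(atlas[tuple(c.voxels.T)])
            labs = [int(v) for v in labs if v != 0]
            if atlas_labels:
                row["atlas_labels"] = ";".join(str(atlas_labels.get(v, v)) for v in labs)
            else:
                row["atlas_labels"] = ";".join(str(v) for v in labs)
        rows.append(row)
    cols = ["rank", "size_voxels", "solidity", "centroid_x", "centroid_y", "centroid_z"]
    if roi is not None:
        cols.append("frac_in_roi")
    if atlas is not None:
        cols.append("atlas_labels")
    return pd.DataFrame(rows, columns=cols)
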