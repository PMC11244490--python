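"""Individual-plant segmentation of normalized bamboo point clouds.

Two complementary strategies, chosen per data source:

* **PCS** (point cloud segmentation, for airborne data): top-down region
  growing seeded at the globally highest unassigned point.  Sweeping from
  the canopy down, each point joins the segment owning its horizontally
  nearest already-assigned point, unless that distance exceeds the spacing
  threshold ``d``, in which case the point seeds a new plant.

* **CSP** (comparative shortest path, for terrestrial and merged data):
  culm-first.  Culms are detected by density clustering (DBSCAN) of the
  horizontal coordinates of points in a low slice band; every remaining
  point is then assigned to the culm with the minimal graph shortest-path
  length through a k-nearest-neighbour graph built on a voxel-subsampled
  cloud.  A second pass re-detects culms inside each first-pass segment at a
  finer neighbourhood radius and splits segments that turn out to contain
  more than one culm.

Heights are read per segment as the maximum normalized z among members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN
from sklearn.neighbors import kneighbors_graph

from .cloud import PointCloud

log = logging.getLogger(__name__)

UNASSIGNED = -1


class SegmentationError(RuntimeError):
    pass


class CulmDetectionError(SegmentationError):
    """No culm cluster found; review the density-clustering parameters."""


@dataclass
class BambooSegment:
    """One detected plant: member points, apex, height, culm position."""

    id: int
    indices: np.ndarray  # member point indices into the segmented cloud
    apex_index: int  # index (into the cloud) of the highest member
    apex_xyz: np.ndarray
    height_m: float
    culm_base_xy: np.ndarray  # (2,) detection location used for matching
    method: str  # {"pcs", "csp"}

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise SegmentationError("segment has no member points")
        if self.height_m <= 0:
            raise SegmentationError("segment height must be positive")


@dataclass
class PcsParams:
    #: spacing threshold d; the field practice is the plot's average plant
    #: spacing, sqrt(plot area / n plants)
    d: float = 1.5
    slab_m: float = 0.2
    min_height_m: float = 1.0
    min_segment_points: int = 50

    def validate(self) -> None:
        if self.d <= 0:
            raise ValueError("PCS spacing threshold d must be > 0")
        if self.slab_m <= 0:
            raise ValueError("slab_m must be > 0")


@dataclass
class CspParams:
    dbscan_min_points: int = 500
    dbscan_radius_m: float = 0.2
    culm_band_m: tuple[float, float] = (0.5, 2.0)
    knn: int = 10
    #: edges longer than this are pruned from the path graph so that an air
    #: gap between neighbouring crowns actually disconnects them
    max_edge_m: float = 0.15
    voxel_m: float = 0.05
    min_segment_points: int = 50
    min_height_m: float = 0.2
    second_pass_radius_scale: float = 0.5
    double_pass: bool = True

    def validate(self) -> None:
        if self.dbscan_min_points < 1:
            raise ValueError("dbscan_min_points must be >= 1")
        if self.dbscan_radius_m <= 0:
            raise ValueError("dbscan_radius_m must be > 0")


@dataclass
class CulmCluster:
    id: int
    indices: np.ndarray
    base_xy: np.ndarray


def _require_normalized(cloud: PointCloud, op: str) -> None:
    if len(cloud) == 0:
        raise SegmentationError(f"{op}: empty cloud")
    if not cloud.meta.get("normalized", False):
        log.warning("%s: cloud is not marked height-normalized; heights assume z above ground", op)


def _build_segments(cloud: PointCloud, labels: np.ndarray, method: str, base_xy_by_label=None,
                    min_points: int = 1) -> list[BambooSegment]:
    segments = []
    out_labels = labels.copy()
    next_id = 1
    for lab in sorted(set(labels[labels != UNASSIGNED])):
        idx = np.where(labels == lab)[0]
        if len(idx) < min_points:
            out_labels[idx] = UNASSIGNED
            continue
        apex_local = idx[np.argmax(cloud.z[idx])]
        apex = cloud.xyz[apex_local]
        if base_xy_by_label is not None and lab in base_xy_by_label:
            base = np.asarray(base_xy_by_label[lab], dtype=float)
        else:
            base = apex[:2].copy()
        segments.append(
            BambooSegment(
                id=next_id,
                indices=idx,
                apex_index=int(apex_local),
                apex_xyz=apex.copy(),
                height_m=float(apex[2]),
                culm_base_xy=base,
                method=method,
            )
        )
        out_labels[idx] = next_id
        next_id += 1
    labels[:] = out_labels
    return segments


# ------------------------------------------------------------------- PCS


def segment_pcs(cloud: PointCloud, params: PcsParams | None = None) -> list[BambooSegment]:
    """Top-down region growing; one seed per locally highest unassigned point."""
    params = params or PcsParams()
    params.validate()
    _require_normalized(cloud, "segment_pcs")
    in_scope = np.where(cloud.z >= params.min_height_m)[0]
    if len(in_scope) == 0:
        raise SegmentationError("no points above the PCS minimum height")
    order = in_scope[np.argsort(-cloud.z[in_scope], kind="stable")]
    xy = cloud.xy
    labels = np.full(len(cloud), UNASSIGNED, dtype=np.int64)

    assigned_xy = np.empty((len(order), 2))
    assigned_seg = np.empty(len(order), dtype=np.int64)
    n_assigned = 0
    tree_size = 0
    tree: cKDTree | None = None
    rebuild_every = 512
    n_segments = 0

    for pt in order:
        p = xy[pt]
        best_d = np.inf
        best_seg = UNASSIGNED
        if tree is not None and tree_size:
            dist, idx = tree.query(p, k=1)
            best_d, best_seg = dist, assigned_seg[idx]
        if n_assigned > tree_size:
            recent = assigned_xy[tree_size:n_assigned]
            d2 = np.sum((recent - p) ** 2, axis=1)
            j = int(np.argmin(d2))
            dr = float(np.sqrt(d2[j]))
            if dr < best_d:
                best_d, best_seg = dr, assigned_seg[tree_size + j]
        if best_d <= params.d:
            labels[pt] = best_seg
        else:
            n_segments += 1
            labels[pt] = n_segments
        assigned_xy[n_assigned] = p
        assigned_seg[n_assigned] = labels[pt]
        n_assigned += 1
        if n_assigned - tree_size >= rebuild_every:
            tree = cKDTree(assigned_xy[:n_assigned])
            tree_size = n_assigned

    return _build_segments(cloud, labels, "pcs", min_points=params.min_segment_points)


# ------------------------------------------------------------------- CSP


def detect_culms(cloud: PointCloud, params: CspParams | None = None,
                 radius_override_m: float | None = None) -> list[CulmCluster]:
    """DBSCAN culm detection on the horizontal coordinates of the slice band."""
    params = params or CspParams()
    params.validate()
    _require_normalized(cloud, "detect_culms")
    lo, hi = params.culm_band_m
    band = np.where((cloud.z >= lo) & (cloud.z < hi))[0]
    if len(band) == 0:
        raise CulmDetectionError(f"no points in the culm band [{lo}, {hi}) m")
    eps = radius_override_m if radius_override_m is not None else params.dbscan_radius_m
    labels = DBSCAN(eps=eps, min_samples=params.dbscan_min_points, algorithm="kd_tree").fit_predict(
        cloud.xy[band]
    )
    raw = []
    for lab in range(labels.max() + 1):
        idx = band[labels == lab]
        raw.append((cloud.xy[idx].mean(axis=0), idx))
    if not raw:
        raise CulmDetectionError(
            "density clustering found no culm cluster; review dbscan_min_points "
            f"(={params.dbscan_min_points}) and dbscan_radius_m (={eps}) against the point density"
        )
    # deterministic ids: sort clusters by centroid
    raw.sort(key=lambda t: (round(t[0][0], 6), round(t[0][1], 6)))
    return [CulmCluster(id=i + 1, indices=idx, base_xy=ctr) for i, (ctr, idx) in enumerate(raw)]


def segment_csp(cloud: PointCloud, culms: list[CulmCluster], params: CspParams | None = None
                ) -> list[BambooSegment]:
    """Assign every point to the culm with minimal shortest-path distance."""
    params = params or CspParams()
    if not culms:
        raise SegmentationError("segment_csp requires at least one culm cluster")
    _require_normalized(cloud, "segment_csp")
    labels = _csp_labels(cloud, culms, params)
    base_by_label = {c.id: c.base_xy for c in culms}
    return _build_segments(cloud, labels, "csp", base_xy_by_label=base_by_label,
                           min_points=params.min_segment_points)


def _csp_labels(cloud: PointCloud, culms: list[CulmCluster], params: CspParams) -> np.ndarray:
    xyz = cloud.xyz
    in_scope = np.where(cloud.z >= params.min_height_m)[0]
    labels = np.full(len(cloud), UNASSIGNED, dtype=np.int64)
    if len(in_scope) == 0:
        return labels

    # voxel-subsampled node set
    voxel = params.voxel_m
    keys = np.floor(xyz[in_scope] / voxel).astype(np.int64)
    uniq, node_of_point = np.unique(keys, axis=0, return_inverse=True)
    nodes = np.zeros((len(uniq), 3))
    np.add.at(nodes, node_of_point, xyz[in_scope])
    counts = np.bincount(node_of_point, minlength=len(uniq))
    nodes /= counts[:, None]

    # seed nodes: voxels containing culm-cluster points (lowest culm id wins)
    node_culm = np.full(len(nodes), -1, dtype=np.int64)
    scope_pos = np.full(len(cloud), -1, dtype=np.int64)
    scope_pos[in_scope] = np.arange(len(in_scope))
    for culm in sorted(culms, key=lambda c: -c.id):
        pos = scope_pos[culm.indices]
        pos = pos[pos >= 0]
        node_culm[node_of_point[pos]] = culm.id
    seed_nodes = np.where(node_culm >= 0)[0]
    if len(seed_nodes) == 0:
        raise SegmentationError("culm clusters contributed no graph nodes")

    k = min(params.knn, len(nodes) - 1)
    if k >= 1:
        graph = kneighbors_graph(nodes, n_neighbors=k, mode="distance")
        if params.max_edge_m is not None:
            graph.data[graph.data > params.max_edge_m] = 0.0
            graph.eliminate_zeros()
        graph = graph.maximum(graph.T)
        dist, _, sources = dijkstra(
            graph, directed=False, indices=seed_nodes, min_only=True, return_predecessors=True
        )
        reached = np.isfinite(dist)
        node_assign = np.full(len(nodes), -1, dtype=np.int64)
        node_assign[reached] = node_culm[sources[reached].astype(np.int64)]
    else:
        node_assign = node_culm.copy()

    # unreachable nodes fall back to the horizontally nearest culm base
    bases = np.vstack([c.base_xy for c in culms])
    culm_ids = np.array([c.id for c in culms])
    missing = node_assign < 0
    if missing.any():
        d2 = ((nodes[missing, None, :2] - bases[None, :, :]) ** 2).sum(axis=2)
        node_assign[missing] = culm_ids[np.argmin(d2, axis=1)]

    labels[in_scope] = node_assign[node_of_point]
    return labels


def segment_csp_double(cloud: PointCloud, params: CspParams | None = None
                       ) -> tuple[list[BambooSegment], dict]:
    """Two-pass CSP: global pass, then per-segment culm re-detection and split.

    The second pass re-examines each first-pass segment at a finer density-
    clustering radius; a segment in which more than one culm is then found is
    re-segmented by shortest paths within its own points.  Well-separated
    stands are a fixed point of the second pass.
    """
    params = params or CspParams()
    culms = detect_culms(cloud, params)
    first = segment_csp(cloud, culms, params)
    if not params.double_pass:
        return first, {"second_pass_splits": 0, "converged": True}
    eps2 = params.dbscan_radius_m * params.second_pass_radius_scale
    final_labels = np.full(len(cloud), UNASSIGNED, dtype=np.int64)
    base_by_label: dict[int, np.ndarray] = {}
    next_label = 1
    splits = 0
    for seg in first:
        sub = cloud.select(seg.indices)
        try:
            sub_culms = detect_culms(sub, params, radius_override_m=eps2)
        except CulmDetectionError:
            sub_culms = []
        if len(sub_culms) >= 2:
            sub_labels = _csp_labels(sub, sub_culms, params)
            splits += 1
            for culm in sub_culms:
                members = seg.indices[sub_labels == culm.id]
                if len(members) == 0:
                    continue
                final_labels[members] = next_label
                base_by_label[next_label] = culm.base_xy
                next_label += 1
            final_labels[seg.indices[sub_labels == UNASSIGNED]] = UNASSIGNED
        else:
            final_labels[seg.indices] = next_label
            base_by_label[next_label] = (
                sub_culms[0].base_xy if sub_culms else seg.culm_base_xy
            )
            next_label += 1
    segments = _build_segments(cloud, final_labels, "csp", base_xy_by_label=base_by_label,
                               min_points=params.min_segment_points)
    info = {"second_pass_splits": splits, "converged": splits == 0}
    if splits == 0:
        log.info("second CSP pass made no change (converged)")
    return segments, info


def extract_height(segment: BambooSegment, cloud: PointCloud) -> float:
    """Plant height: maximum normalized z among the segment's members."""
    if len(segment.indices) == 0:
        raise SegmentationError("cannot extract a height from an empty segment")
    return float(cloud.z[segment.indices].max())
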