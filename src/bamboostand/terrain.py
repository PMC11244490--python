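"""Ground classification, DEM gridding and height normalization.

Ground points are classified with classical progressive TIN densification
(PTD): seed the terrain with per-cell minima on a coarse grid, triangulate,
then iteratively accept points that lie close to their containing facet
(vertical distance threshold) and subtend small angles to the facet plane
from its vertices.  A 0.5 m DEM is gridded from the classified ground points
(per-cell mean, nearest-neighbour void filling) and point heights are
normalized by subtracting the elevation of the containing DEM cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .cloud import PointCloud

log = logging.getLogger(__name__)


class GroundClassificationError(RuntimeError):
    pass


@dataclass
class GroundParams:
    seed_cell_m: float = 2.0
    dist_threshold_m: float = 0.3
    angle_threshold_deg: float = 8.0
    #: facets steeper than this are not treated as terrain during
    #: densification; guards against near-vertical sliver facets formed by
    #: noisy, horizontally near-coincident stem points
    max_facet_slope_deg: float = 45.0
    max_iter: int = 30


@dataclass
class DEMGrid:
    origin: np.ndarray  # (2,) lower-left corner
    cell_size_m: float
    elevation: np.ndarray  # (nrows, ncols), fully filled
    filled_from_data: np.ndarray  # (nrows, ncols) bool, False where void-filled

    @property
    def nrows(self) -> int:
        return self.elevation.shape[0]

    @property
    def ncols(self) -> int:
        return self.elevation.shape[1]

    def cell_index(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the containing cell; outside points clamp to the edge."""
        xy = np.atleast_2d(xy)
        col = np.floor((xy[:, 0] - self.origin[0]) / self.cell_size_m).astype(int)
        row = np.floor((xy[:, 1] - self.origin[1]) / self.cell_size_m).astype(int)
        outside = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        if outside.any():
            log.warning("%d points outside DEM footprint use the nearest cell", int(outside.sum()))
        return np.clip(row, 0, self.nrows - 1), np.clip(col, 0, self.ncols - 1)

    def lookup(self, xy: np.ndarray) -> np.ndarray:
        row, col = self.cell_index(xy)
        return self.elevation[row, col]


def _seed_ground(xyz: np.ndarray, cell: float) -> np.ndarray:
    """Indices of the lowest point in each coarse grid cell."""
    xy = xyz[:, :2]
    ij = np.floor((xy - xy.min(axis=0)) / cell).astype(np.int64)
    key = ij[:, 0] * (ij[:, 1].max() + 1) + ij[:, 1]
    order = np.lexsort((xyz[:, 2], key))
    sk = key[order]
    first = np.ones(len(sk), dtype=bool)
    first[1:] = sk[1:] != sk[:-1]
    return order[first]


def classify_ground(cloud: PointCloud, params: GroundParams | None = None) -> np.ndarray:
    """Boolean ground mask by progressive TIN densification."""
    params = params or GroundParams()
    if len(cloud) == 0:
        raise GroundClassificationError("cannot classify an empty cloud")
    xyz = cloud.xyz
    extent = xyz[:, :2].max(axis=0) - xyz[:, :2].min(axis=0)
    if (extent < params.seed_cell_m).all() and len(cloud) > 1:
        raise GroundClassificationError(
            f"cloud footprint {extent} m is smaller than one {params.seed_cell_m} m seed cell"
        )
    seeds = _seed_ground(xyz, params.seed_cell_m)
    if len(seeds) < 3:
        raise GroundClassificationError(f"only {len(seeds)} seed cells; need >= 3 to build a TIN")
    ground = np.zeros(len(xyz), dtype=bool)
    ground[seeds] = True
    angle_sin = np.sin(np.radians(params.angle_threshold_deg))
    min_nz = np.cos(np.radians(params.max_facet_slope_deg))

    for _ in range(params.max_iter):
        gidx = np.where(ground)[0]
        cand = np.where(~ground)[0]
        if len(cand) == 0:
            break
        tri = Delaunay(xyz[gidx, :2])
        simplex = tri.find_simplex(xyz[cand, :2])
        inside = simplex >= 0
        added = np.zeros(len(cand), dtype=bool)
        if inside.any():
            ci = cand[inside]
            verts = gidx[tri.simplices[simplex[inside]]]  # (k, 3)
            v = xyz[verts]  # (k, 3, 3)
            # facet plane and vertical distance
            n_vec = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
            norm = np.linalg.norm(n_vec, axis=1)
            ok_plane = (norm > 0) & (np.abs(n_vec[:, 2]) >= min_nz * np.maximum(norm, 1e-300))
            p = xyz[ci]
            z_plane = np.full(len(ci), np.nan)
            z_plane[ok_plane] = v[ok_plane, 0, 2] - (
                n_vec[ok_plane, 0] * (p[ok_plane, 0] - v[ok_plane, 0, 0])
                + n_vec[ok_plane, 1] * (p[ok_plane, 1] - v[ok_plane, 0, 1])
            ) / n_vec[ok_plane, 2]
            dvert = np.abs(p[:, 2] - z_plane)
            # angles between facet plane and the lines point->vertex
            un = n_vec / np.maximum(norm, 1e-300)[:, None]
            sines = np.zeros((len(ci), 3))
            for j in range(3):
                dvec = p - v[:, j]
                dlen = np.linalg.norm(dvec, axis=1)
                sines[:, j] = np.abs(np.einsum("ij,ij->i", dvec, un)) / np.maximum(dlen, 1e-12)
            accept = ok_plane & (dvert <= params.dist_threshold_m) & (sines.max(axis=1) <= angle_sin)
            added[inside] = accept
        if not added.any():
            break
        ground[cand[added]] = True

    # points outside the TIN hull: accept if vertically close to nearest ground
    leftovers = np.where(~ground)[0]
    if len(leftovers):
        gidx = np.where(ground)[0]
        tri = Delaunay(xyz[gidx, :2])
        outside = leftovers[tri.find_simplex(xyz[leftovers, :2]) < 0]
        if len(outside):
            tree = cKDTree(xyz[gidx, :2])
            _, nn = tree.query(xyz[outside, :2], k=1)
            dz = np.abs(xyz[outside, 2] - xyz[gidx[nn], 2])
            ground[outside[dz <= params.dist_threshold_m]] = True
    return ground


def build_dem(ground: PointCloud, cell_size_m: float = 0.5) -> DEMGrid:
    """Grid per-cell mean ground elevation; fill voids from the nearest cell."""
    if len(ground) == 0:
        raise ValueError("build_dem needs at least one ground point")
    xy = ground.xy
    z = ground.z
    origin = np.floor(xy.min(axis=0) / cell_size_m) * cell_size_m
    ncols = int(np.floor((xy[:, 0].max() - origin[0]) / cell_size_m)) + 1
    nrows = int(np.floor((xy[:, 1].max() - origin[1]) / cell_size_m)) + 1
    col = np.clip(((xy[:, 0] - origin[0]) / cell_size_m).astype(int), 0, ncols - 1)
    row = np.clip(((xy[:, 1] - origin[1]) / cell_size_m).astype(int), 0, nrows - 1)
    sums = np.zeros((nrows, ncols))
    counts = np.zeros((nrows, ncols))
    np.add.at(sums, (row, col), z)
    np.add.at(counts, (row, col), 1.0)
    filled = counts > 0
    elev = np.zeros_like(sums)
    elev[filled] = sums[filled] / counts[filled]
    if not filled.all():
        rr, cc = np.where(filled)
        vr, vc = np.where(~filled)
        tree = cKDTree(np.column_stack([rr, cc]))
        _, nn = tree.query(np.column_stack([vr, vc]), k=1)
        elev[vr, vc] = elev[rr[nn], cc[nn]]
    return DEMGrid(origin=origin, cell_size_m=cell_size_m, elevation=elev, filled_from_data=filled)


def normalize_heights(cloud: PointCloud, dem: DEMGrid) -> PointCloud:
    """Subtract the containing DEM cell's elevation from each point's z."""
    if dem.elevation.size == 0:
        raise ValueError("empty DEM")
    out = cloud.xyz.copy()
    if len(cloud):
        out[:, 2] = cloud.z - dem.lookup(cloud.xy)
    normalized = cloud.with_xyz(out)
    normalized.meta["normalized"] = True
    return normalized


def write_dem_ascii(dem: DEMGrid, path) -> None:
    """ESRI ASCII grid (row 0 of the array is the southernmost row)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {dem.ncols}\n")
        fh.write(f"nrows {dem.nrows}\n")
        fh.write(f"xllcorner {dem.origin[0]:.6f}\n")
        fh.write(f"yllcorner {dem.origin[1]:.6f}\n")
        fh.write(f"cellsize {dem.cell_size_m:.6f}\n")
        fh.write("NODATA_value -9999\n")
        for r in range(dem.nrows - 1, -1, -1):
            fh.write(" ".join(f"{v:.4f}" for v in dem.elevation[r]) + "\n")
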