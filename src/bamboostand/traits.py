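"""DBH estimation by least-squares cylinder fitting of the breast-height slice.

For each segmented plant the culm points with normalized height in
[1.2, 1.4) m are fitted with a finite-free-length circular cylinder.  The
distance from a point p to the cylinder surface with axis direction a,
axis point c and radius r = 1/k is

    d(p) = || (p - c) - ((p - c) . a) a || - 1/k,

and the fit minimizes sum_i d(p_i)^2 by nonlinear least squares over five
free parameters: two axis-direction components (the axis is parameterized
as (ax, ay, 1)/norm, non-degenerate for near-vertical culms), two axis
offsets in the plane normal to the axis, and the radius.  DBH is 2/k.
A single residual-trimming pass (drop |residual| > 3 x MAD, refit) guards
against leaf and branch returns contaminating the slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .cloud import PointCloud
from .segmentation import BambooSegment


class CylinderFitError(RuntimeError):
    pass


@dataclass
class TraitParams:
    slice_lo_m: float = 1.2
    slice_hi_m: float = 1.4
    min_slice_points: int = 10
    trim: bool = True


@dataclass
class CylinderFit:
    axis: np.ndarray  # unit axis direction
    center: np.ndarray  # point on the axis
    k: float  # reciprocal radius (1/m)
    s: float  # residual scale estimate (= rms residual, m)
    rms_m: float
    n_points: int

    @property
    def radius_m(self) -> float:
        return 1.0 / self.k


@dataclass
class DbhResult:
    dbh_m: float | None
    flag: str  # "" | "too_few_points" | "fit_failed"
    fit: CylinderFit | None
    n_slice_points: int


def slice_culm(cloud: PointCloud, segment: BambooSegment, z_lo: float = 1.2,
               z_hi: float = 1.4) -> PointCloud:
    """Member points with normalized height in [z_lo, z_hi)."""
    if z_lo >= z_hi:
        raise ValueError(f"slice bounds must satisfy z_lo < z_hi, got [{z_lo}, {z_hi})")
    member_z = cloud.z[segment.indices]
    sel = segment.indices[(member_z >= z_lo) & (member_z < z_hi)]
    return cloud.select(sel)


def _frame_normal_to(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e1 = np.array([1.0, 0.0, 0.0]) - a * a[0]
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def _residuals(params: np.ndarray, pts: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    ax, ay, u, v, r = params
    a = np.array([ax, ay, 1.0])
    a /= np.linalg.norm(a)
    e1, e2 = _frame_normal_to(a)
    c = centroid + u * e1 + v * e2
    d = pts - c
    along = d @ a
    radial = np.linalg.norm(d - np.outer(along, a), axis=1)
    return radial - r


def _circle_init(xy: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) circle fit of the horizontal projection."""
    A = np.column_stack([2 * xy[:, 0], 2 * xy[:, 1], np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c0 = sol
    r2 = c0 + cx**2 + cy**2
    return float(cx), float(cy), float(np.sqrt(max(r2, 1e-12)))


def fit_cylinder(slice_cloud: PointCloud, trim: bool = True) -> CylinderFit:
    """Least-squares cylinder through the slice points; DBH = 2 x radius."""
    pts = slice_cloud.xyz
    if len(pts) < 10:
        raise CylinderFitError(f"need >= 10 slice points, got {len(pts)}")
    spread = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    horiz_spread = np.ptp(pts[:, :2], axis=0)
    if max(horiz_spread) < 1e-6 or np.ptp(spread) < 1e-12 and len(np.unique(pts, axis=0)) < 3:
        raise CylinderFitError("degenerate slice geometry (points collinear)")
    centroid = pts.mean(axis=0)
    cx, cy, r0 = _circle_init(pts[:, :2])
    x0 = np.array([0.0, 0.0, cx - centroid[0], cy - centroid[1], r0])

    def solve(p, x_init):
        res = least_squares(_residuals, x_init, args=(p, centroid), method="lm",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000)
        return res

    res = solve(pts, x0)
    if not res.success:
        raise CylinderFitError(f"cylinder fit did not converge: {res.message}")
    used = pts
    if trim:
        resid = _residuals(res.x, pts, centroid)
        med = np.median(resid)
        mad = 1.4826 * np.median(np.abs(resid - med))
        if mad > 0:
            keep = np.abs(resid) <= 3 * mad
            if keep.sum() >= 10 and keep.sum() < len(pts):
                used = pts[keep]
                res = solve(used, res.x)
                if not res.success:
                    raise CylinderFitError(f"cylinder refit did not converge: {res.message}")
    ax, ay, u, v, r = res.x
    if r <= 0:
        raise CylinderFitError(f"fit produced non-positive radius {r}")
    a = np.array([ax, ay, 1.0])
    a /= np.linalg.norm(a)
    e1, e2 = _frame_normal_to(a)
    resid = _residuals(res.x, used, centroid)
    rms = float(np.sqrt(np.mean(resid**2)))
    # Rician debias: with radial noise of scale s the mean distance of noisy
    # surface points from the axis exceeds the true radius by ~s^2/(2r), so
    # the geometric fit overestimates; noise-free fits are unaffected (s = 0)
    r = float(r) - rms**2 / (2.0 * float(r))
    if r <= 0:
        raise CylinderFitError("radius not identifiable (residual scale exceeds radius)")
    return CylinderFit(
        axis=a,
        center=centroid + u * e1 + v * e2,
        k=1.0 / float(r),
        s=rms,
        rms_m=rms,
        n_points=len(used),
    )


def dbh_from_fit(fit: CylinderFit) -> float:
    """DBH in metres: twice the fitted radius (= 2/k)."""
    if fit.k <= 0:
        raise ValueError(f"reciprocal radius must be positive, got {fit.k}")
    return 2.0 / fit.k


def estimate_dbh(cloud: PointCloud, segment: BambooSegment,
                 params: TraitParams | None = None) -> DbhResult:
    """Slice, fit and read off DBH for one segment; flags instead of raising."""
    params = params or TraitParams()
    sl = slice_culm(cloud, segment, params.slice_lo_m, params.slice_hi_m)
    if len(sl) < params.min_slice_points:
        return DbhResult(None, "too_few_points", None, len(sl))
    try:
        fit = fit_cylinder(sl, trim=params.trim)
    except CylinderFitError:
        return DbhResult(None, "fit_failed", None, len(sl))
    return DbhResult(dbh_from_fit(fit), "", fit, len(sl))
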