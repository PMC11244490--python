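"""Coarse-to-fine registration of the TLS cloud into the projected frame.

Coarse: a 7-parameter similarity (Helmert/Bursa-Wolf) transform estimated by
least squares from the paired corner-target coordinates.  The rotation uses
the small-angle matrix form standard in geodesy,

    X = T + (1 + m) * [[1, tz, -ty], [-tz, 1, tx], [ty, -tx, 1]] * X0,

which is linear in the seven parameters once the m*theta cross-terms are
dropped; an optional Gauss-Newton refinement re-solves the exact model from
the linear solution.

Fine: point-to-point ICP of the coarsely aligned TLS cloud (source) onto the
ALS cloud (target) -- nearest-neighbour correspondences inside a rejection
radius, closed-form rigid update (centroid + SVD), iterate until the RMS
correspondence distance stops improving.  Scale is not re-estimated in ICP;
it is fixed by the Helmert step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .cloud import FRAME_LOCAL, FRAME_PROJECTED, FrameError, PointCloud
from .io import ControlPointSet

log = logging.getLogger(__name__)


class DegenerateControlError(ValueError):
    """Control-point geometry does not determine the 7 parameters."""


class CoarseAlignmentError(RuntimeError):
    """ICP found no correspondences; the initial alignment is too poor."""


@dataclass
class HelmertTransform:
    """Seven-parameter similarity transform (translations m, rotations rad)."""

    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0
    theta_x: float = 0.0
    theta_y: float = 0.0
    theta_z: float = 0.0
    m: float = 0.0

    @classmethod
    def identity(cls) -> "HelmertTransform":
        return cls()

    @classmethod
    def from_array(cls, arr) -> "HelmertTransform":
        return cls(*[float(v) for v in arr])

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz, self.theta_x, self.theta_y, self.theta_z, self.m])

    @property
    def rotation_matrix(self) -> np.ndarray:
        tx, ty, tz = self.theta_x, self.theta_y, self.theta_z
        return np.array([[1.0, tz, -ty], [-tz, 1.0, tx], [ty, -tx, 1.0]])

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        t = np.array([self.dx, self.dy, self.dz])
        return t + (1.0 + self.m) * pts @ self.rotation_matrix.T

    def inverse_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        t = np.array([self.dx, self.dy, self.dz])
        inv = np.linalg.inv(self.rotation_matrix)
        return ((pts - t) / (1.0 + self.m)) @ inv.T


@dataclass
class HelmertReport:
    residuals: np.ndarray  # (N, 3) projected-frame misfit at the control points
    rms_m: float
    refined: bool


def estimate_helmert(control: ControlPointSet, refine: bool = True) -> tuple[HelmertTransform, HelmertReport]:
    """Least-squares Helmert parameters from paired control coordinates.

    Solves the linearized model first (exact up to m*theta cross-terms), then
    optionally polishes with Gauss-Newton on the exact small-angle form so
    noise-free pairs are recovered to numerical precision.
    """
    local = control.local
    proj = control.projected
    n = len(control)
    A = np.zeros((3 * n, 7))
    x0, y0, z0 = local[:, 0], local[:, 1], local[:, 2]
    A[0::3, 0] = 1.0
    A[1::3, 1] = 1.0
    A[2::3, 2] = 1.0
    A[0::3, 4] = -z0
    A[0::3, 5] = y0
    A[1::3, 3] = z0
    A[1::3, 5] = -x0
    A[2::3, 3] = -y0
    A[2::3, 4] = x0
    A[0::3, 6] = x0
    A[1::3, 6] = y0
    A[2::3, 6] = z0
    b = (proj - local).ravel()
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 7:
        raise DegenerateControlError(
            f"control geometry is rank-deficient (rank {rank} < 7); "
            "targets must not be collinear"
        )
    refined = False
    if refine:

        def fun(params):
            t = HelmertTransform.from_array(params)
            return (t.apply_points(local) - proj).ravel()

        res = least_squares(fun, sol, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        sol = res.x
        refined = True
    transform = HelmertTransform.from_array(sol)
    residuals = transform.apply_points(local) - proj
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1)))) if n else 0.0
    return transform, HelmertReport(residuals=residuals, rms_m=rms, refined=refined)


def apply_helmert(transform: HelmertTransform, cloud: PointCloud) -> PointCloud:
    """Map a local-frame cloud into the projected frame."""
    if cloud.frame != FRAME_LOCAL:
        raise FrameError(f"apply_helmert expects a local-frame cloud, got {cloud.frame!r}")
    return cloud.with_xyz(transform.apply_points(cloud.xyz), frame=FRAME_PROJECTED)


# ------------------------------------------------------------------- ICP


@dataclass
class RigidTransform:
    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.R.T + self.t

    def apply(self, cloud: PointCloud) -> PointCloud:
        return cloud.with_xyz(self.apply_points(cloud.xyz))

    def compose_after(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply `other` first)."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def rotation_angle_rad(self) -> float:
        c = (np.trace(self.R) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass
class IcpParams:
    max_iter: int = 50
    tol_m: float = 1e-6
    rejection_radius_m: float = 1.0
    #: shrink the rejection radius towards ~3 x current RMS each iteration so
    #: points without a true counterpart in the other cloud (e.g. culm returns
    #: absent from the airborne scan) stop steering the fit; floor keeps
    #: enough correspondences under noise
    adaptive_rejection: bool = True
    min_rejection_radius_m: float = 0.05
    voxel_size_m: float | None = 0.05


@dataclass
class IcpResult:
    transform: RigidTransform
    rms_m: float
    n_iterations: int
    converged: bool
    rms_history: list[float] = field(default_factory=list)


def voxel_downsample(xyz: np.ndarray, voxel: float) -> np.ndarray:
    """One representative (centroid) per occupied voxel, in voxel-key order."""
    keys = np.floor(xyz / voxel).astype(np.int64)
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    sk = keys[order]
    boundaries = np.ones(len(sk), dtype=bool)
    boundaries[1:] = (sk[1:] != sk[:-1]).any(axis=1)
    group = np.cumsum(boundaries) - 1
    n_groups = group[-1] + 1 if len(group) else 0
    sums = np.zeros((n_groups, 3))
    np.add.at(sums, group, xyz[order])
    counts = np.bincount(group, minlength=n_groups)
    return sums / counts[:, None]


def icp_refine(source: PointCloud, target: PointCloud, params: IcpParams | None = None) -> IcpResult:
    """Rigidly refine `source` onto `target`; both must be projected-frame."""
    params = params or IcpParams()
    for name, c in (("source", source), ("target", target)):
        if c.frame != FRAME_PROJECTED:
            raise FrameError(f"icp_refine {name} must be in the projected frame")
        if len(c) == 0:
            raise ValueError(f"icp_refine {name} cloud is empty")
    src = source.xyz
    tgt = target.xyz
    if params.voxel_size_m:
        src = voxel_downsample(src, params.voxel_size_m)
        tgt = voxel_downsample(tgt, params.voxel_size_m)
    tree = cKDTree(tgt)
    current = RigidTransform.identity()
    history: list[float] = []
    prev_rms = np.inf
    converged = False
    n_done = 0
    radius = params.rejection_radius_m
    for it in range(params.max_iter):
        moved = current.apply_points(src)
        dist, idx = tree.query(moved, k=1, distance_upper_bound=radius)
        valid = np.isfinite(dist)
        if not valid.any():
            if it == 0:
                raise CoarseAlignmentError(
                    "no correspondences within the rejection radius; coarse alignment too poor"
                )
            break
        rms = float(np.sqrt(np.mean(dist[valid] ** 2)))
        if rms > prev_rms:  # reject the step that made things worse
            break
        history.append(rms)
        n_done = it + 1
        if prev_rms - rms < params.tol_m:
            prev_rms = rms
            converged = True
            break
        prev_rms = rms
        if params.adaptive_rejection:
            radius = min(radius, max(3.0 * rms, params.min_rejection_radius_m))
        p = moved[valid]
        q = tgt[idx[valid]]
        cp, cq = p.mean(axis=0), q.mean(axis=0)
        H = (p - cp).T @ (q - cq)
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R_upd = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        t_upd = cq - R_upd @ cp
        current = RigidTransform(R_upd, t_upd).compose_after(current)
    return IcpResult(
        transform=current,
        rms_m=prev_rms if np.isfinite(prev_rms) else float(history[-1]),
        n_iterations=n_done,
        converged=converged,
        rms_history=history,
    )


def align_from_files(tls_path, als_path, control_path, out_path,
                     icp_params: IcpParams | None = None) -> dict:
    """File-level coarse+fine alignment: write the aligned TLS cloud and
    return a JSON-able report (7 parameters, ICP iterations, final RMS)."""
    from . import io as _io

    tls = _io.read_point_cloud(tls_path, frame=FRAME_LOCAL)
    als = _io.read_point_cloud(als_path)
    control = _io.read_control_points(control_path)
    transform, report = estimate_helmert(control)
    coarse = apply_helmert(transform, tls)
    result = icp_refine(coarse, als, icp_params)
    aligned = result.transform.apply(coarse)
    _io.write_point_cloud(aligned, out_path)
    return {
        "helmert": {
            "dx": transform.dx, "dy": transform.dy, "dz": transform.dz,
            "theta_x": transform.theta_x, "theta_y": transform.theta_y,
            "theta_z": transform.theta_z, "m": transform.m,
            "control_rms_m": report.rms_m,
        },
        "icp": {
            "iterations": result.n_iterations,
            "final_rms_m": result.rms_m,
            "converged": result.converged,
        },
        "output": str(out_path),
    }


def merge_clouds(a: PointCloud, b: PointCloud) -> PointCloud:
    """Concatenate two same-frame clouds, preserving per-point source tags."""
    if a.frame != b.frame:
        raise FrameError(f"cannot merge clouds in frames {a.frame!r} and {b.frame!r}")
    return PointCloud.concat([a, b])
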