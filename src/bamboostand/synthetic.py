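"""Synthetic moso-bamboo stand generator and LiDAR renderers.

The generator produces labelled ground truth for square sample plots
(default 10 m x 10 m, 37-52 plants, hilly terrain) and renders them the way
an airborne scanner (ALS) and a terrestrial scanner (TLS) would see them:

* ALS samples top-down at ~600 pts/m^2 -- dense in the canopy, almost no
  returns on the culms (canopy obstruction), but reliable ground returns.
* TLS samples bottom-up -- dense on culms and the lower crown, sparse to
  absent at crown tops, with per-plant azimuthal culm occlusion and ground
  shadows behind culms; it is delivered in a local frame related to the
  projected frame by a known 7-parameter similarity transform, together with
  corner control points whose projected coordinates carry GNSS-like noise.

Culms are tapered cylinders (constant radius DBH/2 below 1.3 m, linear
taper to zero at the apex) with a random arching lean of a few degrees;
crowns are pointed-dome point shells (thin leader at the top, like a real
moso crown) whose apex coincides with the culm apex, shrunk per plant so
that neighbouring crowns keep a small air gap (crown shyness).
Every rendered non-ground point carries the generating plant's id in the
``plant`` attribute so downstream tests can use it as an oracle; pipeline
stages never read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .cloud import FRAME_LOCAL, FRAME_PROJECTED, PointCloud
from .io import ControlPointSet

PART_GROUND = 0
PART_CULM = 1
PART_CROWN = 2

BREAST_HEIGHT_M = 1.3


class UnplaceableStandError(RuntimeError):
    """min_spacing_m leaves no room for the requested number of plants."""


@dataclass
class StandConfig:
    """Ground-truth stand parameters (lengths in metres, angles in degrees)."""

    plot_size_m: tuple[float, float] = (10.0, 10.0)
    n_plants: int = 40
    dbh_mean_m: float = 0.10
    dbh_sd_m: float = 0.015
    dbh_min_m: float = 0.04
    #: height = allometry_coef * DBH^allometry_exp * LogNormal(0, height_scatter)
    allometry_coef: float = 45.0
    allometry_exp: float = 0.55
    height_scatter: float = 0.05
    crown_radius_m: float = 0.9
    crown_depth_frac: float = 0.35
    #: fraction of crown returns from interior foliage/branches rather than
    #: the outer shell; keeps each crown graph-connected to its own culm
    crown_interior_frac: float = 0.35
    #: crown shyness: neighbouring crowns keep at least this air gap; each
    #: plant's crown radius shrinks to fit its nearest-neighbour distance
    crown_shy_gap_m: float = 0.25
    crown_radius_min_m: float = 0.3
    min_spacing_m: float = 1.0
    max_lean_deg: float = 3.5
    ground_slope_deg: float = 10.0
    ground_bump_amp_m: float = 0.05
    edge_margin_m: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        w, h = self.plot_size_m
        if w <= 0 or h <= 0:
            raise ValueError("plot size must be positive")
        if self.n_plants < 0:
            raise ValueError("n_plants must be >= 0")
        if self.min_spacing_m <= 0:
            raise ValueError("min_spacing_m must be > 0")
        if not 0 < self.crown_depth_frac < 1:
            raise ValueError("crown_depth_frac must be in (0, 1)")
        for name in ("dbh_mean_m", "dbh_sd_m", "crown_radius_m", "allometry_coef"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class StandTruth:
    """One simulated stand: per-plant truth, analytic ground, corner targets."""

    config: StandConfig
    ids: np.ndarray  # (n,)
    base_xy: np.ndarray  # (n, 2)
    dbh_m: np.ndarray  # (n,)
    height_m: np.ndarray  # (n,)
    crown_radius_m: np.ndarray  # (n,)
    lean_xy: np.ndarray  # (n, 2) horizontal axis offset per metre of height
    corner_targets: np.ndarray  # (4, 3) projected

    @property
    def n_plants(self) -> int:
        return len(self.ids)

    def ground_z(self, xy: np.ndarray) -> np.ndarray:
        """Analytic terrain: inclined plane (slope along +x) plus smooth bumps."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        slope = np.tan(np.radians(self.config.ground_slope_deg))
        amp = self.config.ground_bump_amp_m
        z = slope * xy[:, 0] + amp * np.sin(2 * np.pi * xy[:, 0] / 7.3) * np.cos(2 * np.pi * xy[:, 1] / 5.11)
        return z

    def culm_axis_xy(self, i: int, h: np.ndarray) -> np.ndarray:
        """Horizontal culm-axis position at vertical height h above the base."""
        return self.base_xy[i] + np.outer(np.asarray(h, dtype=float), self.lean_xy[i])

    def culm_radius(self, i: int, h: np.ndarray) -> np.ndarray:
        """Taper: constant DBH/2 below breast height, linear to 0 at the apex."""
        h = np.asarray(h, dtype=float)
        r0 = self.dbh_m[i] / 2.0
        top = self.height_m[i]
        r = np.where(
            h <= BREAST_HEIGHT_M,
            r0,
            r0 * np.clip((top - h) / max(top - BREAST_HEIGHT_M, 1e-9), 0.0, 1.0),
        )
        return r

    def to_inventory(self):
        import pandas as pd

        from .io import ReferenceInventory

        return ReferenceInventory(
            pd.DataFrame(
                {
                    "id": self.ids,
                    "x": self.base_xy[:, 0],
                    "y": self.base_xy[:, 1],
                    "dbh_m": self.dbh_m,
                    "height_m": self.height_m,
                }
            )
        )


@dataclass
class ScannerConfig:
    """Rendering parameters for one scanning mode.

    The occlusion profile is a logistic in normalized height hn = h/H:
    ALS retention rises with hn (canopy-dense, culm-sparse), TLS retention
    falls (culm-dense, crown-top-sparse).  ``top_cut_range`` draws a per-plant
    hard crown-top cutoff for TLS; ``culm_gap_deg`` removes a random azimuth
    sector of each culm (occlusion by foliage between scanner and culm);
    ``ground_shadow_m`` removes ground returns near culm bases (TLS shadowing).
    """

    mode: str  # {"als", "tls"}
    density_pts_per_m2: float
    noise_sd_m: float
    ground_fraction: float
    culm_fraction: float
    occl_mid: float
    occl_width: float
    occl_floor: float
    culm_height_decay: float = 0.0
    top_cut_range: Optional[tuple[float, float]] = None
    culm_gap_deg: float = 0.0
    ground_shadow_m: float = 0.0
    seed: int = 1

    def validate(self) -> None:
        if self.mode not in ("als", "tls"):
            raise ValueError("mode must be 'als' or 'tls'")
        if self.density_pts_per_m2 <= 0:
            raise ValueError("density must be > 0")
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be >= 0")

    @classmethod
    def als(cls, **overrides) -> "ScannerConfig":
        cfg = cls(
            mode="als",
            density_pts_per_m2=600.0,
            noise_sd_m=0.02,
            ground_fraction=0.22,
            culm_fraction=0.30,
            occl_mid=0.5,
            occl_width=0.10,
            occl_floor=0.02,
        )
        return replace(cfg, **overrides)

    @classmethod
    def tls(cls, **overrides) -> "ScannerConfig":
        cfg = cls(
            mode="tls",
            density_pts_per_m2=6000.0,
            noise_sd_m=0.005,
            ground_fraction=0.12,
            culm_fraction=0.60,
            occl_mid=0.80,
            occl_width=0.06,
            occl_floor=0.0,
            culm_height_decay=0.6,
            top_cut_range=(0.85, 1.0),
            culm_gap_deg=120.0,
            ground_shadow_m=0.6,
        )
        return replace(cfg, **overrides)

    def retention(self, hn: np.ndarray) -> np.ndarray:
        """Keep-probability as a function of normalized height."""
        hn = np.asarray(hn, dtype=float)
        if self.mode == "als":
            core = 1.0 / (1.0 + np.exp(-(hn - self.occl_mid) / self.occl_width))
        else:
            core = 1.0 / (1.0 + np.exp(-(self.occl_mid - hn) / self.occl_width))
        return self.occl_floor + (1.0 - self.occl_floor) * core


def generate_stand(config: StandConfig) -> StandTruth:
    """Place plants by rejection sampling and draw correlated DBH/height."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    w, h = config.plot_size_m
    inset = min(config.edge_margin_m, w / 4, h / 4)
    positions: list[np.ndarray] = []
    max_attempts = 200 * max(config.n_plants, 1)
    attempts = 0
    while len(positions) < config.n_plants:
        if attempts >= max_attempts:
            raise UnplaceableStandError(
                f"could not place {config.n_plants} plants with spacing >= "
                f"{config.min_spacing_m} m in a {w} x {h} m plot after {max_attempts} attempts"
            )
        attempts += 1
        cand = rng.uniform([inset, inset], [w - inset, h - inset])
        if all(np.hypot(*(cand - p)) >= config.min_spacing_m for p in positions):
            positions.append(cand)
    base_xy = np.asarray(positions).reshape(-1, 2)

    n = config.n_plants
    dbh = np.empty(n)
    for i in range(n):
        while True:
            d = rng.normal(config.dbh_mean_m, config.dbh_sd_m)
            if d >= config.dbh_min_m and abs(d - config.dbh_mean_m) <= 3 * config.dbh_sd_m:
                dbh[i] = d
                break
    height = config.allometry_coef * dbh**config.allometry_exp * np.exp(
        rng.normal(0.0, config.height_scatter, size=n)
    )
    tilt = np.radians(rng.uniform(0.0, config.max_lean_deg, size=n))
    azim = rng.uniform(0.0, 2 * np.pi, size=n)
    lean_xy = np.tan(tilt)[:, None] * np.column_stack([np.cos(azim), np.sin(azim)])

    crown_r = np.full(n, config.crown_radius_m)
    if n > 1:
        d_nn, _ = cKDTree(base_xy).query(base_xy, k=2)
        crown_r = np.clip(
            0.5 * (d_nn[:, 1] - config.crown_shy_gap_m),
            config.crown_radius_min_m,
            config.crown_radius_m,
        )

    truth = StandTruth(
        config=config,
        ids=np.arange(1, n + 1),
        base_xy=base_xy,
        dbh_m=dbh,
        height_m=height,
        crown_radius_m=crown_r,
        lean_xy=lean_xy,
        corner_targets=np.zeros((4, 3)),
    )
    corners_xy = np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])
    truth.corner_targets = np.column_stack([corners_xy, truth.ground_z(corners_xy)])
    return truth


def _render_projected(truth: StandTruth, scanner: ScannerConfig) -> PointCloud:
    scanner.validate()
    rng = np.random.default_rng(scanner.seed)
    cfg = truth.config
    w, h = cfg.plot_size_m
    margin = cfg.edge_margin_m
    area = (w + 2 * margin) * (h + 2 * margin)
    budget = scanner.density_pts_per_m2 * w * h

    # --- ground
    n_ground = int(round(scanner.density_pts_per_m2 * area * scanner.ground_fraction))
    gxy = rng.uniform([-margin, -margin], [w + margin, h + margin], size=(n_ground, 2))
    if scanner.ground_shadow_m > 0 and truth.n_plants > 0:
        tree = cKDTree(truth.base_xy)
        dist, _ = tree.query(gxy, k=1)
        gxy = gxy[dist > scanner.ground_shadow_m]
    ground_pts = np.column_stack([gxy, truth.ground_z(gxy)])
    parts = [ground_pts]
    plant_labels = [np.full(len(ground_pts), -1, dtype=np.int64)]
    part_labels = [np.full(len(ground_pts), PART_GROUND, dtype=np.int64)]
    hag_labels = [np.zeros(len(ground_pts))]

    if truth.n_plants > 0:
        weights = truth.height_m / truth.height_m.sum()
        plant_budget = np.maximum(1, np.round(budget * (1 - scanner.ground_fraction) * weights)).astype(int)
        if scanner.top_cut_range is not None:
            top_cut = rng.uniform(*scanner.top_cut_range, size=truth.n_plants)
        else:
            top_cut = np.full(truth.n_plants, np.inf)
        gap_center = rng.uniform(0.0, 2 * np.pi, size=truth.n_plants)
        gap_half = np.radians(scanner.culm_gap_deg) / 2.0

        for i in range(truth.n_plants):
            H = truth.height_m[i]
            z0 = float(truth.ground_z(truth.base_xy[i][None, :])[0])
            n_culm = int(round(plant_budget[i] * scanner.culm_fraction))
            n_crown = plant_budget[i] - n_culm

            # culm: tapered tube, optional bottom-weighted height sampling
            q = rng.uniform(0.0, 1.0, size=n_culm)
            c = scanner.culm_height_decay
            if c > 0:
                # inverse CDF of f(u) ∝ 1 - c*u on [0, 1]
                u = (1.0 - np.sqrt(1.0 - c * (2.0 - c) * q)) / c
            else:
                u = q
            hh = u * H
            phi = rng.uniform(0.0, 2 * np.pi, size=n_culm)
            if gap_half > 0:
                ang = np.abs((phi - gap_center[i] + np.pi) % (2 * np.pi) - np.pi)
                keep = ang > gap_half
                hh, phi = hh[keep], phi[keep]
            rr = truth.culm_radius(i, hh)
            axis_xy = truth.culm_axis_xy(i, hh)
            cx = axis_xy[:, 0] + rr * np.cos(phi)
            cy = axis_xy[:, 1] + rr * np.sin(phi)
            culm = np.column_stack([cx, cy, z0 + hh])
            keep_culm = rng.uniform(size=len(culm)) < scanner.retention(hh / H)
            keep_culm &= hh / H <= top_cut[i]
            culm = culm[keep_culm]

            # crown: half-ellipsoid shell, apex at the culm apex
            depth = cfg.crown_depth_frac * H
            Rc = truth.crown_radius_m[i]
            # pointed-dome crown profile r(w) = Rc (1 - w)^p with the apex at
            # w = 1: moso crowns end in a thin arching leader, so foliage area
            # (and hence sampling density) vanishes towards the very top.
            # Heights sampled with the matching area weight p(w) ∝ (1 - w)^p.
            p_apex = 0.75
            wdir = 1.0 - rng.uniform(size=n_crown) ** (1.0 / (1.0 + p_apex))
            psi = rng.uniform(0.0, 2 * np.pi, size=n_crown)
            shell = 1.0 + rng.normal(0.0, 0.05, size=n_crown)
            interior = rng.uniform(size=n_crown) < cfg.crown_interior_frac
            shell[interior] = rng.uniform(0.15, 1.0, size=int(interior.sum()))
            horiz = np.clip(1.0 - wdir, 0.0, 1.0) ** p_apex
            center_h = H - depth
            center_xy = truth.base_xy[i] + truth.lean_xy[i] * center_h
            # shell jitter thickens the envelope horizontally only, so no
            # crown point exceeds the true plant height
            crown_h = center_h + depth * wdir
            crown = np.column_stack(
                [
                    center_xy[0] + Rc * horiz * np.cos(psi) * shell,
                    center_xy[1] + Rc * horiz * np.sin(psi) * shell,
                    z0 + crown_h,
                ]
            )
            keep = rng.uniform(size=n_crown) < scanner.retention(crown_h / H)
            keep &= crown_h / H <= top_cut[i]
            crown = crown[keep]

            parts.extend([culm, crown])
            plant_labels.extend(
                [np.full(len(culm), truth.ids[i]), np.full(len(crown), truth.ids[i])]
            )
            part_labels.extend(
                [np.full(len(culm), PART_CULM), np.full(len(crown), PART_CROWN)]
            )
            hag_labels.extend([hh[keep_culm], crown_h[keep]])

    xyz = np.vstack(parts)
    plant = np.concatenate(plant_labels)
    part = np.concatenate(part_labels)
    hag = np.concatenate(hag_labels)
    if scanner.noise_sd_m > 0:
        xyz = xyz + rng.normal(0.0, scanner.noise_sd_m, size=xyz.shape)
    classification = np.where(part == PART_GROUND, 2, 1).astype(np.uint8)
    return PointCloud(
        xyz,
        frame=FRAME_PROJECTED,
        attrs={
            "plant": plant,
            "part": part,
            "hag": hag,
            "classification": classification,
            "source": np.full(len(xyz), scanner.mode),
        },
    )


def render_als(truth: StandTruth, scanner: ScannerConfig | None = None) -> PointCloud:
    """Render the stand as an airborne scan in the projected frame."""
    scanner = scanner or ScannerConfig.als()
    if scanner.mode != "als":
        raise ValueError("render_als requires scanner.mode == 'als'")
    return _render_projected(truth, scanner)


def render_tls(
    truth: StandTruth,
    scanner: ScannerConfig | None = None,
    true_transform=None,
    control_noise_sd_m: float = 0.05,
) -> tuple[PointCloud, ControlPointSet]:
    """Render a terrestrial scan in a local frame plus noisy corner controls.

    The local frame is the inverse image of the projected frame under
    ``true_transform`` (identity if omitted).  The returned control set pairs
    each corner target's exact local coordinates with its projected
    coordinates perturbed by Gaussian noise of sd ``control_noise_sd_m``
    (emulating RTK error under canopy).
    """
    from .alignment import HelmertTransform

    scanner = scanner or ScannerConfig.tls()
    if scanner.mode != "tls":
        raise ValueError("render_tls requires scanner.mode == 'tls'")
    if true_transform is None:
        true_transform = HelmertTransform.identity()
    cloud = _render_projected(truth, scanner)
    local = cloud.with_xyz(true_transform.inverse_points(cloud.xyz), frame=FRAME_LOCAL)
    rng = np.random.default_rng(scanner.seed + 77_003)
    noisy_proj = truth.corner_targets + rng.normal(0.0, control_noise_sd_m, size=(4, 3))
    controls = ControlPointSet(
        ids=[f"T{i+1}" for i in range(4)],
        local=true_transform.inverse_points(truth.corner_targets),
        projected=noisy_proj,
    )
    return local, controls
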