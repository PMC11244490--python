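"""End-to-end orchestration: simulate -> align -> normalize -> segment ->
traits -> evaluate.

The happy path mirrors the field workflow: a TLS cloud delivered in a local
frame is coarsely georeferenced with a Helmert transform estimated from the
corner targets, refined with ICP against the ALS cloud, and merged.  Each
requested data source (als, tls, merged) is then ground-filtered,
height-normalized, segmented (PCS for the airborne cloud, double-pass CSP
for the terrestrial and merged clouds), measured (height for all sources,
DBH for tls/merged) and scored against the reference inventory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, io, terrain, traits
from .alignment import (HelmertTransform, IcpParams, apply_helmert, estimate_helmert,
                        icp_refine, merge_clouds)
from .cloud import PointCloud
from .segmentation import CspParams, PcsParams, extract_height, segment_csp_double, segment_pcs
from .synthetic import ScannerConfig, StandConfig, StandTruth, generate_stand, render_als, render_tls

log = logging.getLogger(__name__)

#: plot presets: plants per 10 m x 10 m plot (3700/4500/5200 per hm^2)
PRESETS = {"A1": 37, "A2": 45, "A3": 52}

DEFAULT_TRUE_TRANSFORM = HelmertTransform(
    dx=25.0, dy=-12.0, dz=4.0, theta_x=0.004, theta_y=-0.003, theta_z=0.005, m=4e-5
)


@dataclass
class PipelineConfig:
    stand: StandConfig = field(default_factory=StandConfig)
    sources: tuple[str, ...] = ("als", "tls", "merged")
    seed: int = 0
    plot_id: str = "synthetic"
    control_noise_sd_m: float = 0.05
    true_transform: HelmertTransform = field(default_factory=lambda: DEFAULT_TRUE_TRANSFORM)
    als_scanner: ScannerConfig | None = None  # None -> ScannerConfig.als(seed=seed+1)
    tls_scanner: ScannerConfig | None = None  # None -> ScannerConfig.tls(seed=seed+2)
    icp: IcpParams = field(default_factory=IcpParams)
    ground: terrain.GroundParams = field(default_factory=terrain.GroundParams)
    pcs: PcsParams | None = None  # None -> d from the reference spacing
    csp: CspParams = field(default_factory=CspParams)
    trait: traits.TraitParams = field(default_factory=traits.TraitParams)
    dem_cell_m: float = 0.5
    match_threshold_m: float | None = None  # None -> average spacing
    max_ground_classify_points: int = 200_000
    out_dir: str | None = None

    @classmethod
    def preset(cls, name: str, seed: int = 0, **overrides) -> "PipelineConfig":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        stand = StandConfig(n_plants=PRESETS[name], seed=seed)
        return cls(stand=stand, seed=seed, plot_id=name, **overrides)


@dataclass
class SimulatedPlot:
    truth: StandTruth
    als: PointCloud
    tls_local: PointCloud
    controls: io.ControlPointSet


def simulate_plot(config: PipelineConfig) -> SimulatedPlot:
    stand = replace(config.stand, seed=config.seed)
    truth = generate_stand(stand)
    als_scanner = config.als_scanner or ScannerConfig.als(seed=config.seed + 1)
    tls_scanner = config.tls_scanner or ScannerConfig.tls(seed=config.seed + 2)
    als = render_als(truth, als_scanner)
    tls_local, controls = render_tls(
        truth,
        tls_scanner,
        true_transform=config.true_transform,
        control_noise_sd_m=config.control_noise_sd_m,
    )
    return SimulatedPlot(truth=truth, als=als, tls_local=tls_local, controls=controls)


@dataclass
class AlignmentOutcome:
    helmert: HelmertTransform
    helmert_rms_m: float
    icp_rms_m: float
    coarse_rms_m: float
    icp_iterations: int
    tls_aligned: PointCloud
    merged: PointCloud


def align_sources(als: PointCloud, tls_local: PointCloud, controls: io.ControlPointSet,
                  icp_params: IcpParams | None = None) -> AlignmentOutcome:
    """Helmert coarse + ICP fine alignment of TLS onto ALS, then merge."""
    helmert, report = estimate_helmert(controls)
    tls_coarse = apply_helmert(helmert, tls_local)
    result = icp_refine(tls_coarse, als, icp_params or IcpParams())
    tls_aligned = result.transform.apply(tls_coarse)
    merged = merge_clouds(als, tls_aligned)
    coarse = result.rms_history[0] if result.rms_history else float("nan")
    return AlignmentOutcome(
        helmert=helmert,
        helmert_rms_m=report.rms_m,
        icp_rms_m=result.rms_m,
        coarse_rms_m=coarse,
        icp_iterations=result.n_iterations,
        tls_aligned=tls_aligned,
        merged=merged,
    )


def normalize_source(cloud: PointCloud, config: PipelineConfig) -> tuple[PointCloud, terrain.DEMGrid]:
    """Classify ground (on a bounded subsample), grid the DEM, normalize."""
    work = cloud
    if len(cloud) > config.max_ground_classify_points:
        rng = np.random.default_rng(config.seed + 9)
        pick = rng.choice(len(cloud), size=config.max_ground_classify_points, replace=False)
        work = cloud.select(np.sort(pick))
    mask = terrain.classify_ground(work, config.ground)
    dem = terrain.build_dem(work.select(mask), cell_size_m=config.dem_cell_m)
    return terrain.normalize_heights(cloud, dem), dem


def _analyze_source(name: str, normalized: PointCloud, truth: StandTruth,
                    config: PipelineConfig) -> dict:
    inventory = truth.to_inventory()
    area = config.stand.plot_size_m[0] * config.stand.plot_size_m[1]
    threshold = config.match_threshold_m or evaluation.default_match_threshold(area, len(inventory))

    if name == "als":
        pcs = config.pcs or PcsParams(d=threshold)
        segments = segment_pcs(normalized, pcs)
    else:
        segments, _ = segment_csp_double(normalized, config.csp)

    positions = np.array([s.culm_base_xy for s in segments]).reshape(-1, 2)
    match = evaluation.match_detections(positions, inventory, threshold)
    acc = evaluation.detection_metrics(match)

    heights_est, heights_ref = [], []
    dbh_est, dbh_ref = [], []
    ref_heights = inventory.table["height_m"].to_numpy(float)
    ref_dbh = inventory.table["dbh_m"].to_numpy(float)
    for det_i, ref_i in match.pairs:
        seg = segments[det_i]
        heights_est.append(extract_height(seg, normalized))
        heights_ref.append(ref_heights[ref_i])
        if name != "als":
            res = traits.estimate_dbh(normalized, seg, config.trait)
            if res.dbh_m is not None:
                dbh_est.append(res.dbh_m)
                dbh_ref.append(ref_dbh[ref_i])

    row = {
        "plot": config.plot_id,
        "source": name,
        "n": len(inventory),
        "n_segments": len(segments),
        "nt": match.nt,
        "nc": match.nc,
        "no": match.no,
        "r_pct": acc.r_pct,
        "p_pct": acc.p_pct,
        "f": acc.f_2dp,
    }
    if len(heights_est) >= 2:
        h = evaluation.regression_metrics(heights_est, heights_ref)
        row["height_rmse_m"] = h.rmse
        row["height_r2"] = h.r2
    if len(dbh_est) >= 2:
        d = evaluation.regression_metrics(dbh_est, dbh_ref)
        row["dbh_rmse_m"] = d.rmse
        row["dbh_r2"] = d.r2
        row["n_dbh"] = len(dbh_est)
    return row


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested sources end-to-end and return the accuracy report."""
    for s in config.sources:
        if s not in ("als", "tls", "merged"):
            raise ValueError(f"unknown source {s!r}")
    needs_alignment = any(s in config.sources for s in ("tls", "merged"))
    sim = simulate_plot(config)
    report: dict = {"plot": config.plot_id, "seed": config.seed, "rows": []}

    clouds: dict[str, PointCloud] = {"als": sim.als}
    if needs_alignment:
        if sim.controls is None:
            raise ValueError("tls/merged sources require control points")
        outcome = align_sources(sim.als, sim.tls_local, sim.controls, config.icp)
        clouds["tls"] = outcome.tls_aligned
        clouds["merged"] = outcome.merged
        report["alignment"] = {
            "helmert": outcome.helmert.as_array().tolist(),
            "helmert_rms_m": outcome.helmert_rms_m,
            "icp_coarse_rms_m": outcome.coarse_rms_m,
            "icp_final_rms_m": outcome.icp_rms_m,
            "icp_iterations": outcome.icp_iterations,
        }

    for name in config.sources:
        log.info("pipeline %s: source %s (%d points)", config.plot_id, name, len(clouds[name]))
        normalized, _ = normalize_source(clouds[name], config)
        report["rows"].append(_analyze_source(name, normalized, sim.truth, config))

    if config.out_dir:
        evaluation.plot_report(report["rows"], config.out_dir,
                               parameters={"seed": config.seed, "plot": config.plot_id})
        with open(Path(config.out_dir) / "report.json", "w") as fh:
            json.dump(evaluation._jsonable(report), fh, indent=2, sort_keys=True)
    return report


def make_fixtures(preset: str, out_dir, seed: int = 0) -> dict[str, str]:
    """Write a preset stand's clouds, control points and truth inventory."""
    config = PipelineConfig.preset(preset, seed=seed)
    sim = simulate_plot(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "als_las": out / f"{preset}_als.las",
        "als_xyz": out / f"{preset}_als.xyz",
        "tls_las": out / f"{preset}_tls_local.las",
        "controls": out / f"{preset}_controls.csv",
        "inventory": out / f"{preset}_inventory.csv",
    }
    io.write_las(sim.als, paths["als_las"])
    io.write_xyz(sim.als, paths["als_xyz"])
    io.write_las(sim.tls_local, paths["tls_las"])
    io.write_control_points(sim.controls, paths["controls"])
    io.write_inventory(sim.truth.to_inventory(), paths["inventory"])
    return {k: str(v) for k, v in paths.items()}


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file with per-stage sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    if "preset" in raw:
        cfg = PipelineConfig.preset(raw["preset"], seed=int(raw.get("seed", 0)))
    if "stand" in raw:
        cfg.stand = replace(cfg.stand, **raw["stand"])
    for key in ("seed", "plot_id", "control_noise_sd_m", "dem_cell_m",
                "match_threshold_m", "out_dir", "max_ground_classify_points"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "sources" in raw:
        cfg.sources = tuple(raw["sources"])
    if "icp" in raw:
        cfg.icp = replace(cfg.icp, **raw["icp"])
    if "ground" in raw:
        cfg.ground = replace(cfg.ground, **raw["ground"])
    if "pcs" in raw:
        cfg.pcs = PcsParams(**raw["pcs"])
    if "csp" in raw:
        cfg.csp = replace(cfg.csp, **raw["csp"])
    if "trait" in raw:
        cfg.trait = replace(cfg.trait, **raw["trait"])
    return cfg
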