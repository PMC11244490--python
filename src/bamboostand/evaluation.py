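"""Detection matching and accuracy metrics.

A detection is correct when its location (segment apex for PCS, culm base
for CSP) lies within a distance threshold of an unmatched reference plant;
matching is greedy globally-nearest-first and one-to-one.  From the counts
N_t (correct), N_c (commission) and N_o (omission):

    recall    r = N_t / (N_t + N_o)
    precision p = N_t / (N_t + N_c)
    F         = 2 r p / (r + p)

Trait accuracy over the correctly segmented plants is summarized by
RMSE = sqrt(sum_i (y_i - y_i')^2 / n) and by R^2, the squared Pearson
correlation of the linear regression of estimated on measured values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import ReferenceInventory


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]  # (detection index, reference index)
    nt: int
    nc: int
    no: int

    def __post_init__(self) -> None:
        if min(self.nt, self.nc, self.no) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class PlotAccuracy:
    r: float
    p: float
    f: float

    @property
    def r_pct(self) -> float:
        return round(100.0 * self.r, 2)

    @property
    def p_pct(self) -> float:
        return round(100.0 * self.p, 2)

    @property
    def f_2dp(self) -> float:
        return round(self.f, 2)


@dataclass
class TraitAccuracy:
    rmse: float
    r2: float
    n: int
    flag: str = ""


def match_detections(detected_xy: np.ndarray, reference: ReferenceInventory,
                     threshold_m: float) -> MatchResult:
    """Greedy globally-nearest-first one-to-one matching under a distance cap."""
    if threshold_m <= 0:
        raise ValueError("threshold_m must be > 0")
    detected_xy = np.asarray(detected_xy, dtype=float).reshape(-1, 2)
    ref_xy = reference.positions
    n_det, n_ref = len(detected_xy), len(ref_xy)
    pairs: list[tuple[int, int]] = []
    if n_det and n_ref:
        dist = cdist(detected_xy, ref_xy)
        di, ri = np.where(dist <= threshold_m)
        order = np.argsort(dist[di, ri], kind="stable")
        used_det = np.zeros(n_det, dtype=bool)
        used_ref = np.zeros(n_ref, dtype=bool)
        for k in order:
            d, r = int(di[k]), int(ri[k])
            if not used_det[d] and not used_ref[r]:
                used_det[d] = used_ref[r] = True
                pairs.append((d, r))
    nt = len(pairs)
    return MatchResult(pairs=pairs, nt=nt, nc=n_det - nt, no=n_ref - nt)


def detection_metrics(m: MatchResult) -> PlotAccuracy:
    """Recall, precision and F score from the matching counts."""
    if m.nt + m.no <= 0:
        raise ValueError("no reference plants (Nt + No == 0)")
    r = m.nt / (m.nt + m.no)
    p = m.nt / (m.nt + m.nc) if (m.nt + m.nc) > 0 else 0.0
    f = 2 * r * p / (r + p) if (r + p) > 0 else 0.0
    return PlotAccuracy(r=r, p=p, f=f)


def regression_metrics(estimated, reference) -> TraitAccuracy:
    """RMSE and R^2 of estimated vs field-measured trait values."""
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if len(est) != len(ref):
        raise ValueError("estimated and reference lengths differ")
    if len(est) < 2:
        raise ValueError("need at least 2 pairs for regression metrics")
    rmse = float(np.sqrt(np.mean((est - ref) ** 2)))
    if np.std(ref) == 0 or np.std(est) == 0:
        return TraitAccuracy(rmse=rmse, r2=float("nan"), n=len(est), flag="zero_variance")
    r = float(np.corrcoef(est, ref)[0, 1])
    return TraitAccuracy(rmse=rmse, r2=r**2, n=len(est))


def default_match_threshold(plot_area_m2: float, n_reference: int) -> float:
    """Average plant spacing, read as sqrt(plot area / n plants)."""
    if n_reference < 1:
        raise ValueError("need at least one reference plant")
    return float(np.sqrt(plot_area_m2 / n_reference))


# --------------------------------------------------------------- reporting


def summary_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-plot x per-source rows into a detection-accuracy table."""
    df = pd.DataFrame(rows)
    cols = [c for c in (
        "plot", "source", "n", "n_segments", "nt", "nc", "no",
        "r_pct", "p_pct", "f", "height_rmse_m", "height_r2", "dbh_rmse_m", "dbh_r2",
    ) if c in df.columns]
    return df[cols]


def plot_report(rows: list[dict], out_dir, parameters: dict | None = None) -> dict:
    """Write the JSON + CSV accuracy report for a set of plot/source runs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = summary_table(rows)
    table.to_csv(out_dir / "accuracy.csv", index=False)
    payload = {
        "rows": _jsonable(rows),
        "parameters": _jsonable(parameters or {}),
    }
    with open(out_dir / "accuracy.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return payload


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
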