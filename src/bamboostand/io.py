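"""Readers and writers for the formats the pipeline touches.

Point clouds travel as LAS 1.2 (point format 0) or whitespace XYZ text;
control points and reference inventories are plain CSV with explicit headers.
All lengths are SI metres.  The LAS support here is a deliberately small
reader/writer pair covering exactly what the pipeline round-trips:
coordinates (scaled int32 per the LAS spec), the classification code, a
source tag stashed in ``user_data`` (1 = als, 2 = tls) and a segmentation
label stashed in ``point_source_id`` (stored as label + 1 so that 0 means
"unlabelled").
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import FRAME_PROJECTED, PointCloud

log = logging.getLogger(__name__)

_LAS_HEADER_SIZE = 227  # LAS 1.2
_LAS_PF0 = np.dtype(
    [
        ("x", "<i4"),
        ("y", "<i4"),
        ("z", "<i4"),
        ("intensity", "<u2"),
        ("flags", "u1"),
        ("classification", "u1"),
        ("scan_angle", "i1"),
        ("user_data", "u1"),
        ("point_source_id", "<u2"),
    ]
)
_SOURCE_CODES = {"": 0, "als": 1, "tls": 2}
_SOURCE_NAMES = {v: k for k, v in _SOURCE_CODES.items()}


class PointCloudParseError(ValueError):
    """Malformed point-cloud file."""


# ---------------------------------------------------------------- XYZ text


def read_xyz(path, frame: str = FRAME_PROJECTED) -> PointCloud:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise PointCloudParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts[:3]])
            except ValueError as exc:
                raise PointCloudParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        log.warning("empty point-cloud file %s", path)
        return PointCloud(np.empty((0, 3)), frame=frame)
    arr = np.asarray(rows, dtype=float)
    if not np.isfinite(arr).all():
        bad = int(np.where(~np.isfinite(arr).all(axis=1))[0][0])
        raise PointCloudParseError(f"{path}: non-finite coordinate in record {bad + 1}")
    return PointCloud(arr, frame=frame)


def write_xyz(cloud: PointCloud, path, precision: int = 6) -> None:
    np.savetxt(path, cloud.xyz, fmt=f"%.{precision}f")


# ---------------------------------------------------------------- LAS 1.2


def write_las(cloud: PointCloud, path) -> None:
    n = len(cloud)
    scale = 0.001
    offset = np.floor(cloud.xyz.min(axis=0)) if n else np.zeros(3)
    ints = np.round((cloud.xyz - offset) / scale).astype(np.int64)
    if n and (np.abs(ints) > 2**31 - 1).any():
        raise ValueError("coordinates exceed LAS int32 range at 1 mm resolution")
    rec = np.zeros(n, dtype=_LAS_PF0)
    rec["x"], rec["y"], rec["z"] = ints.T if n else (0, 0, 0)
    rec["flags"] = 0b00001001  # single return, first of one
    if "classification" in cloud.attrs:
        rec["classification"] = cloud.attrs["classification"].astype(np.uint8)
    if "source" in cloud.attrs:
        src = cloud.attrs["source"]
        rec["user_data"] = [_SOURCE_CODES.get(str(s), 0) for s in src]
    if "label" in cloud.attrs:
        rec["point_source_id"] = (cloud.attrs["label"].astype(np.int64) + 1).clip(0, 65535)
    mins = cloud.xyz.min(axis=0) if n else offset
    maxs = cloud.xyz.max(axis=0) if n else offset
    header = struct.pack(
        "<4sHHL HH 8sB B 32s 32s HHH LL B HL 5L 12d",
        b"LASF", 0, 0, 0, 0, 0, b"\0" * 8, 1, 2,
        b"bamboostand".ljust(32, b"\0"), b"bamboostand".ljust(32, b"\0"),
        1, 1, _LAS_HEADER_SIZE, _LAS_HEADER_SIZE, 0, 0, _LAS_PF0.itemsize, n,
        n, 0, 0, 0, 0,
        scale, scale, scale, offset[0], offset[1], offset[2],
        maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2],
    )
    assert len(header) == _LAS_HEADER_SIZE
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(rec.tobytes())


def read_las(path, frame: str = FRAME_PROJECTED) -> PointCloud:
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _LAS_HEADER_SIZE or raw[:4] != b"LASF":
        raise PointCloudParseError(f"{path}: not a LAS file (bad signature)")
    offset_to_points = struct.unpack_from("<L", raw, 96)[0]
    point_format = raw[104]
    record_len = struct.unpack_from("<H", raw, 105)[0]
    n = struct.unpack_from("<L", raw, 107)[0]
    scales = struct.unpack_from("<3d", raw, 131)
    offsets = struct.unpack_from("<3d", raw, 155)
    if point_format not in (0, 1):
        raise PointCloudParseError(f"{path}: unsupported LAS point format {point_format}")
    if record_len < _LAS_PF0.itemsize:
        raise PointCloudParseError(f"{path}: record length {record_len} too small")
    body = raw[offset_to_points : offset_to_points + n * record_len]
    if len(body) != n * record_len:
        raise PointCloudParseError(f"{path}: truncated point records ({len(body)} bytes for {n} points)")
    if record_len == _LAS_PF0.itemsize:
        rec = np.frombuffer(body, dtype=_LAS_PF0)
    else:  # skip trailing bytes (e.g. GPS time of format 1)
        rec = np.frombuffer(body, dtype=np.uint8).reshape(n, record_len)[:, : _LAS_PF0.itemsize]
        rec = rec.copy().view(_LAS_PF0).reshape(n)
    xyz = np.column_stack(
        [rec["x"] * scales[0] + offsets[0], rec["y"] * scales[1] + offsets[1], rec["z"] * scales[2] + offsets[2]]
    )
    attrs: dict[str, np.ndarray] = {"classification": rec["classification"].copy()}
    if rec["user_data"].any():
        attrs["source"] = np.array([_SOURCE_NAMES.get(int(c), "") for c in rec["user_data"]])
    if rec["point_source_id"].any():
        attrs["label"] = rec["point_source_id"].astype(np.int64) - 1
    return PointCloud(xyz, frame=frame, attrs=attrs)


def read_point_cloud(path, format: str | None = None, frame: str = FRAME_PROJECTED) -> PointCloud:
    fmt = format or _infer_format(path)
    if fmt == "las":
        return read_las(path, frame=frame)
    if fmt == "xyz":
        return read_xyz(path, frame=frame)
    raise ValueError(f"unknown point-cloud format {fmt!r}")


def write_point_cloud(cloud: PointCloud, path, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "las":
        write_las(cloud, path)
    elif fmt == "xyz":
        write_xyz(cloud, path)
    else:
        raise ValueError(f"unknown point-cloud format {fmt!r}")


def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    return {"las": "las", "xyz": "xyz", "txt": "xyz"}.get(suffix, suffix)


# ---------------------------------------------------------------- tables


@dataclass
class ControlPointSet:
    """Paired corner-target coordinates: exact local frame vs surveyed projected frame."""

    ids: list[str]
    local: np.ndarray  # (N, 3)
    projected: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.local = np.asarray(self.local, dtype=float).reshape(-1, 3)
        self.projected = np.asarray(self.projected, dtype=float).reshape(-1, 3)
        if len(self.ids) != len(self.local) or len(self.local) != len(self.projected):
            raise ValueError("ids/local/projected lengths differ")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate control-point target IDs")
        if not (np.isfinite(self.local).all() and np.isfinite(self.projected).all()):
            raise ValueError("control coordinates must be finite")
        if len(self.ids) < 3:
            raise ValueError(
                "at least 3 full 3-D control pairs are required to estimate the "
                f"7-parameter transform (got {len(self.ids)})"
            )

    def __len__(self) -> int:
        return len(self.ids)


def read_control_points(path) -> ControlPointSet:
    df = pd.read_csv(path)
    required = ["id", "local_x", "local_y", "local_z", "proj_x", "proj_y", "proj_z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"control-point CSV missing columns: {missing}")
    return ControlPointSet(
        ids=[str(i) for i in df["id"]],
        local=df[["local_x", "local_y", "local_z"]].to_numpy(float),
        projected=df[["proj_x", "proj_y", "proj_z"]].to_numpy(float),
    )


def write_control_points(control: ControlPointSet, path) -> None:
    pd.DataFrame(
        {
            "id": control.ids,
            "local_x": control.local[:, 0],
            "local_y": control.local[:, 1],
            "local_z": control.local[:, 2],
            "proj_x": control.projected[:, 0],
            "proj_y": control.projected[:, 1],
            "proj_z": control.projected[:, 2],
        }
    ).to_csv(path, index=False)


@dataclass
class ReferenceInventory:
    """Field-surveyed plants: id, projected stem position, DBH and height in metres."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["id", "x", "y"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"inventory missing columns: {missing}")
        if not np.isfinite(self.table[["x", "y"]].to_numpy(float)).all():
            raise ValueError("inventory positions must be finite")
        for col in ("dbh_m", "height_m"):
            if col in self.table.columns:
                vals = self.table[col].to_numpy(float)
                present = ~np.isnan(vals)
                if (vals[present] <= 0).any():
                    raise ValueError(f"inventory {col} must be positive where present")
        if self.table["id"].duplicated().any():
            raise ValueError("duplicate plant IDs in inventory")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(float)


def read_inventory(path) -> ReferenceInventory:
    return ReferenceInventory(pd.read_csv(path))


def write_inventory(inv: ReferenceInventory, path) -> None:
    inv.table.to_csv(path, index=False)
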