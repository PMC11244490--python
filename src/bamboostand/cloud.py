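"""Point-cloud container shared by every pipeline stage.

A :class:`PointCloud` is an N x 3 array of metric coordinates plus optional
per-point attributes (classification code, source tag, segmentation label,
simulator ground-truth labels) and a coordinate-frame tag.  The projected
frame is any metric CRS; the package treats the CRS as an opaque label and
never reprojects.  Axes are right-handed with z up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

FRAME_LOCAL = "local"
FRAME_PROJECTED = "projected"
_FRAMES = (FRAME_LOCAL, FRAME_PROJECTED)


class FrameError(ValueError):
    """Raised when an operation receives a cloud in the wrong frame."""


@dataclass
class PointCloud:
    xyz: np.ndarray
    frame: str = FRAME_PROJECTED
    attrs: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.size == 0:
            self.xyz = self.xyz.reshape(0, 3)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError(f"xyz must be (N, 3), got {self.xyz.shape}")
        if not np.isfinite(self.xyz).all():
            raise ValueError("point coordinates must be finite (NaN/Inf found)")
        if self.frame not in _FRAMES:
            raise FrameError(f"unknown frame {self.frame!r}; expected one of {_FRAMES}")
        n = len(self.xyz)
        for key, val in self.attrs.items():
            arr = np.asarray(val)
            if len(arr) != n:
                raise ValueError(f"attribute {key!r} has length {len(arr)} != {n} points")
            self.attrs[key] = arr

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    @property
    def xy(self) -> np.ndarray:
        return self.xyz[:, :2]

    def select(self, index: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or integer index, carrying attributes along."""
        index = np.asarray(index)
        return PointCloud(
            self.xyz[index],
            frame=self.frame,
            attrs={k: v[index] for k, v in self.attrs.items()},
            meta=dict(self.meta),
        )

    def with_xyz(self, xyz: np.ndarray, frame: str | None = None) -> "PointCloud":
        """Same attributes, new coordinates (used by frame transforms)."""
        return PointCloud(
            np.asarray(xyz, dtype=float),
            frame=self.frame if frame is None else frame,
            attrs={k: v.copy() for k, v in self.attrs.items()},
            meta=dict(self.meta),
        )

    @staticmethod
    def concat(clouds: Iterable["PointCloud"]) -> "PointCloud":
        clouds = list(clouds)
        if not clouds:
            return PointCloud(np.empty((0, 3)))
        frame = clouds[0].frame
        for c in clouds:
            if c.frame != frame:
                raise FrameError(f"cannot concatenate frames {frame!r} and {c.frame!r}")
        keys = set().union(*(c.attrs.keys() for c in clouds))
        attrs = {}
        for key in keys:
            parts = []
            for c in clouds:
                if key in c.attrs:
                    parts.append(np.asarray(c.attrs[key]))
                else:
                    ref = next(a[key] for a in (x.attrs for x in clouds) if key in a)
                    fill = -1 if np.issubdtype(ref.dtype, np.integer) else (
                        np.nan if np.issubdtype(ref.dtype, np.floating) else ""
                    )
                    parts.append(np.full(len(c), fill, dtype=ref.dtype))
            attrs[key] = np.concatenate(parts)
        meta = dict(clouds[0].meta)
        return PointCloud(np.vstack([c.xyz for c in clouds]), frame=frame, attrs=attrs, meta=meta)
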