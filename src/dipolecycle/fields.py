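"""Containers for per-frame displacement-rate fields and cell geometry.

A :class:`VectorFieldSeries` holds scattered sample positions (um, y-up,
origin at the field center) and displacement-rate vectors (um/min) for a
sequence of frames; it is the ``u_i(n)`` of the multipole formulas.  A
:class:`CellGeometrySeries` holds the per-frame cell center, polarization
axis and nucleus front/back positions used to orient kymographs and
multipole projections.

Both round-trip through a tab-separated text dialect with a commented
``# key = value`` metadata header, shared by the synthetic generator and
the tracker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["VectorFieldSeries", "CellGeometrySeries", "read_metadata_header"]

_FIELD_COLUMNS = ["frame", "x_um", "y_um", "u_um_per_min", "v_um_per_min"]
_GEOM_COLUMNS = [
    "frame",
    "center_x_um",
    "center_y_um",
    "axis_x",
    "axis_y",
    "front_x_um",
    "front_y_um",
    "back_x_um",
    "back_y_um",
]


def _write_tsv(path: str | Path, df: pd.DataFrame, meta: Mapping[str, object]) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_metadata_header(path: str | Path) -> dict[str, str]:
    """Parse leading ``# key = value`` comment lines of a tabular file."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


@dataclass
class VectorFieldSeries:
    """Scattered displacement-rate samples per frame, in physical units."""

    data: pd.DataFrame                       # columns _FIELD_COLUMNS
    dt: float                                # frame interval, min
    pixel_size: float | None = None          # um/px, if image-derived
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(_FIELD_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"field table missing columns {sorted(missing)}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        values = self.data[_FIELD_COLUMNS[1:]].to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValueError("field contains non-finite values")

    @classmethod
    def from_frames(
        cls,
        frames: Iterable[Mapping[str, np.ndarray]],
        dt: float,
        pixel_size: float | None = None,
        meta: Mapping[str, object] | None = None,
    ) -> "VectorFieldSeries":
        """Build from per-frame dicts with keys x, y, u, v (um, um/min)."""
        parts = []
        for k, fr in enumerate(frames):
            parts.append(
                pd.DataFrame(
                    {
                        "frame": np.full(len(fr["x"]), k, dtype=int),
                        "x_um": np.asarray(fr["x"], dtype=float),
                        "y_um": np.asarray(fr["y"], dtype=float),
                        "u_um_per_min": np.asarray(fr["u"], dtype=float),
                        "v_um_per_min": np.asarray(fr["v"], dtype=float),
                    }
                )
            )
        data = pd.concat(parts, ignore_index=True)
        return cls(data=data, dt=dt, pixel_size=pixel_size, meta=dict(meta or {}))

    @property
    def n_frames(self) -> int:
        return int(self.data["frame"].max()) + 1 if len(self.data) else 0

    def frame(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """(positions (N,2), rates (N,2)) of frame n."""
        sel = self.data[self.data["frame"] == n]
        pos = sel[["x_um", "y_um"]].to_numpy()
        vec = sel[["u_um_per_min", "v_um_per_min"]].to_numpy()
        return pos, vec

    def frames(self) -> Iterable[tuple[int, np.ndarray, np.ndarray]]:
        for n, sel in self.data.groupby("frame"):
            yield int(n), sel[["x_um", "y_um"]].to_numpy(), sel[
                ["u_um_per_min", "v_um_per_min"]
            ].to_numpy()

    def write_tsv(self, path: str | Path) -> None:
        meta = {"dt_min": self.dt, **self.meta}
        if self.pixel_size is not None:
            meta["pixel_size_um"] = self.pixel_size
        _write_tsv(path, self.data[_FIELD_COLUMNS], meta)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "VectorFieldSeries":
        meta = read_metadata_header(path)
        data = pd.read_csv(path, sep="\t", comment="#")
        dt = float(meta.pop("dt_min"))
        pixel_size = float(meta.pop("pixel_size_um")) if "pixel_size_um" in meta else None
        return cls(data=data, dt=dt, pixel_size=pixel_size, meta=meta)


@dataclass
class CellGeometrySeries:
    """Per-frame cell center, unit polarization axis, nucleus front/back."""

    data: pd.DataFrame  # columns _GEOM_COLUMNS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(_GEOM_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"geometry table missing columns {sorted(missing)}")
        norms = np.hypot(self.data["axis_x"], self.data["axis_y"])
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("axis vectors must be unit-norm")

    @classmethod
    def constant(
        cls,
        n_frames: int,
        center: tuple[float, float] = (0.0, 0.0),
        axis: tuple[float, float] = (1.0, 0.0),
        front: tuple[float, float] | None = None,
        back: tuple[float, float] | None = None,
        nucleus_halfgap: float = 7.5,
    ) -> "CellGeometrySeries":
        """Time-independent geometry; front/back default to +-halfgap along the axis."""
        ax = np.asarray(axis, dtype=float)
        ax = ax / np.hypot(*ax)
        c = np.asarray(center, dtype=float)
        fr = np.asarray(front, dtype=float) if front is not None else c + nucleus_halfgap * ax
        bk = np.asarray(back, dtype=float) if back is not None else c - nucleus_halfgap * ax
        data = pd.DataFrame(
            {
                "frame": np.arange(n_frames),
                "center_x_um": c[0],
                "center_y_um": c[1],
                "axis_x": ax[0],
                "axis_y": ax[1],
                "front_x_um": fr[0],
                "front_y_um": fr[1],
                "back_x_um": bk[0],
                "back_y_um": bk[1],
            }
        )
        return cls(data=data)

    def row(self, n: int) -> pd.Series:
        sel = self.data[self.data["frame"] == n]
        if sel.empty:
            raise KeyError(f"no geometry for frame {n}")
        return sel.iloc[0]

    def write_tsv(self, path: str | Path) -> None:
        _write_tsv(path, self.data[_GEOM_COLUMNS], self.meta)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CellGeometrySeries":
        meta = read_metadata_header(path)
        return cls(data=pd.read_csv(path, sep="\t", comment="#"), meta=meta)
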