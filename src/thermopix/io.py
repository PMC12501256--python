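"""File-format plumbing: CSV / PNG rasters with JSON sidecars.

Binary masks export as 0/1 integer CSV and 1-bit PNG; real-valued grids as
float CSV and 16-bit PNG (min-max scaled, with the scaling recorded in the
sidecar so the PNG round-trips to physical units).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
from PIL import Image

__all__ = [
    "write_binary_grid",
    "read_binary_grid",
    "write_real_grid",
    "read_real_grid",
    "write_sidecar",
    "read_sidecar",
]


def write_sidecar(path: str | Path, metadata: dict[str, Any]) -> Path:
    path = Path(path).with_suffix(".json")
    path.write_text(json.dumps(metadata, indent=1, sort_keys=True))
    return path


def read_sidecar(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(Path(path).with_suffix(".json")).read_text())


def write_binary_grid(
    grid: np.ndarray,
    stem: str | Path,
    metadata: dict[str, Any] | None = None,
    png: bool = True,
) -> dict[str, Path]:
    """Write a {0,1} grid as CSV (and optionally 1-bit PNG) plus sidecar."""
    grid = np.asarray(grid)
    if not np.isin(grid, (0, 1)).all():
        raise ValueError("grid must be binary {0,1}")
    stem = Path(stem)
    out: dict[str, Path] = {}
    csv_path = stem.with_suffix(".csv")
    np.savetxt(csv_path, grid.astype(int), fmt="%d", delimiter=",")
    out["csv"] = csv_path
    if png:
        png_path = stem.with_suffix(".png")
        Image.fromarray((grid * 255).astype(np.uint8)).convert("1").save(png_path)
        out["png"] = png_path
    if metadata is not None:
        out["json"] = write_sidecar(stem, dict(metadata, dtype="binary"))
    return out


def read_binary_grid(stem: str | Path) -> np.ndarray:
    return np.loadtxt(Path(stem).with_suffix(".csv"), delimiter=",", dtype=np.int64, ndmin=2)


def write_real_grid(
    grid: np.ndarray,
    stem: str | Path,
    metadata: dict[str, Any] | None = None,
    png: bool = True,
) -> dict[str, Path]:
    """Write a real grid as float CSV and min-max scaled 16-bit PNG."""
    grid = np.asarray(grid, dtype=float)
    stem = Path(stem)
    out: dict[str, Path] = {}
    csv_path = stem.with_suffix(".csv")
    np.savetxt(csv_path, grid, fmt="%.12g", delimiter=",")
    out["csv"] = csv_path
    lo, hi = float(grid.min()), float(grid.max())
    meta = dict(metadata or {}, dtype="real", png_scale_min=lo, png_scale_max=hi)
    if png:
        scale = (grid - lo) / (hi - lo) if hi > lo else np.zeros_like(grid)
        png_path = stem.with_suffix(".png")
        Image.fromarray((scale * 65535).astype(np.uint16)).save(png_path)
        out["png"] = png_path
    out["json"] = write_sidecar(stem, meta)
    return out


def read_real_grid(stem: str | Path) -> np.ndarray:
    return np.loadtxt(Path(stem).with_suffix(".csv"), delimiter=",", dtype=float, ndmin=2)
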