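"""Sampling uniformity, spatial resolution, and reconstruction fidelity.

The diagonal compressed scan is designed to spread the measured bucket
signals nearly uniformly over the 2D-reshaped signal array, so that every
unmeasured signal has a measured neighbor close by — the property that
makes discrete Laplace interpolation accurate.  ``max_neighbor_distance``
quantifies this: for each unsampled site, the torus distance to its
nearest sampled site, compared here between the diagonal scan and a
conventional linear scan of the same length.

Spatial resolution follows the slit-profile convention: the mean intensity
profile across a narrow slit is normalized to [0, 1] and the resolution is
the number of pixels exceeding 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruct import ReconstructedImage

__all__ = [
    "UniformityReport",
    "max_neighbor_distance",
    "spatial_resolution",
    "slit_profile",
    "image_error",
]

_METRICS = ("chebyshev", "euclidean", "manhattan")


@dataclass(frozen=True)
class UniformityReport:
    """Nearest-sampled-neighbor distances of all unsampled sites."""

    distances: np.ndarray
    maximum: float
    histogram: np.ndarray
    bin_edges: np.ndarray
    metric: str

    @property
    def empty(self) -> bool:
        return self.distances.size == 0


def _torus_deltas(extent: int) -> np.ndarray:
    d = np.arange(extent)
    return np.minimum(d, extent - d)


def max_neighbor_distance(
    measured_rows: np.ndarray,
    p: int,
    q: int,
    metric: str = "chebyshev",
    bins: int = 10,
) -> UniformityReport:
    """Distance from each unsampled site to its nearest sampled site.

    Linear signal indices are reshaped row-major onto the p x q grid and
    distances are taken on the torus (both axes wrap, matching the modular
    neighbor structure of the cyclic measurement).  Metrics: chebyshev
    (default), euclidean, manhattan.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    n = p * q
    measured = np.unique(np.asarray(measured_rows, dtype=np.int64))
    if measured.size and (measured.min() < 0 or measured.max() >= n):
        raise ValueError("measured row index out of range")
    sampled = np.zeros(n, dtype=bool)
    sampled[measured] = True
    unsampled = np.flatnonzero(~sampled)
    if unsampled.size == 0 or measured.size == 0:
        empty = np.array([])
        hist, edges = np.histogram(empty, bins=bins)
        return UniformityReport(empty, 0.0, hist, edges, metric)

    ui, uj = unsampled // q, unsampled % q
    mi, mj = measured // q, measured % q
    di = np.minimum(np.abs(ui[:, None] - mi[None, :]), p - np.abs(ui[:, None] - mi[None, :]))
    dj = np.minimum(np.abs(uj[:, None] - mj[None, :]), q - np.abs(uj[:, None] - mj[None, :]))
    if metric == "chebyshev":
        d = np.maximum(di, dj)
    elif metric == "manhattan":
        d = di + dj
    else:
        d = np.sqrt(di.astype(float) ** 2 + dj.astype(float) ** 2)
    nearest = d.min(axis=1).astype(float)
    hist, edges = np.histogram(nearest, bins=bins)
    return UniformityReport(nearest, float(nearest.max()), hist, edges, metric)


def slit_profile(grid: np.ndarray, angle_deg: float) -> np.ndarray:
    """Mean intensity along lines parallel to a slit, normalized to [0, 1].

    For a vertical slit (0 deg) the profile runs across columns; for a
    horizontal slit (90 deg) across rows; for +/-45 deg the means are taken
    along the grid diagonals.
    """
    g = np.asarray(grid, dtype=float)
    if angle_deg == 0.0:
        prof = g.mean(axis=0)
    elif angle_deg == 90.0:
        prof = g.mean(axis=1)
    elif angle_deg in (45.0, -45.0):
        p, q = g.shape
        ii, jj = np.mgrid[0:p, 0:q]
        key = (ii + jj) if angle_deg == 45.0 else (ii - jj) + (q - 1)
        prof = np.array([g[key == k].mean() for k in range(p + q - 1)])
    else:
        raise ValueError("angle must be one of 0, 90, 45, -45 degrees")
    lo, hi = prof.min(), prof.max()
    if hi - lo == 0:
        raise ValueError("flat image: profile has zero dynamic range")
    return (prof - lo) / (hi - lo)


def spatial_resolution(
    recon: ReconstructedImage | np.ndarray, angle_deg: float = 0.0
) -> int:
    """Pixels of the normalized slit profile exceeding 0.5."""
    g = recon.grid if isinstance(recon, ReconstructedImage) else recon
    prof = slit_profile(g, angle_deg)
    return int((prof > 0.5).sum())


def image_error(
    recon: ReconstructedImage | np.ndarray, truth: np.ndarray
) -> dict[str, float]:
    """RMSE, max-abs error, and RMSE normalized by the truth's range."""
    g = recon.grid if isinstance(recon, ReconstructedImage) else np.asarray(recon, dtype=float)
    t = np.asarray(truth, dtype=float)
    if g.shape != t.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {t.shape}")
    diff = g - t
    rmse = float(np.sqrt((diff**2).mean()))
    rng = float(t.max() - t.min())
    return {
        "rmse": rmse,
        "max_abs": float(np.abs(diff).max()),
        "nrmse": rmse / rng if rng > 0 else float("nan"),
    }
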