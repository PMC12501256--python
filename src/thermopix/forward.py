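"""Bucket-signal acquisition: optical inner products plus detector noise.

Each bucket signal is the inner product of the scene with one encoding
pattern, ``y_u = sum_v S[u, v] * x_v`` with the scene flattened row-major.
The chopper / lock-in detection chain is modeled as a scalar gain and
i.i.d. Gaussian noise on the bucket signals; the lock-in output is a single
scalar per mask position, so no waveform-level simulation is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .masks import CodingScheme, diagonal_scan_rows
from .smatrix import SMatrix

__all__ = ["ThermalScene", "ScanRecord", "simulate_scan", "simulate_full_scan"]


@dataclass(frozen=True)
class ThermalScene:
    """Ground-truth radiance grid of p x q pixels (arbitrary linear units).

    ``temperature_K`` optionally carries the source-temperature grid from
    which the radiance was derived through the calibration model.
    """

    radiance: np.ndarray
    temperature_K: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.radiance, dtype=float)
        if r.ndim != 2:
            raise ValueError(f"radiance must be 2D, got shape {r.shape}")
        if (r < 0).any():
            raise ValueError("radiance must be non-negative")
        object.__setattr__(self, "radiance", r)

    @property
    def shape(self) -> tuple[int, int]:
        return self.radiance.shape


@dataclass(frozen=True)
class ScanRecord:
    """Measured bucket signals with their measurement-row indices."""

    measured_rows: np.ndarray
    bucket: np.ndarray
    noise_sigma: float = 0.0
    gain: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.bucket) != len(self.measured_rows):
            raise ValueError("bucket and measured_rows must have equal length")

    @property
    def m(self) -> int:
        return len(self.bucket)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "measured_rows": np.asarray(self.measured_rows).tolist(),
            "bucket": np.asarray(self.bucket).tolist(),
            "noise_sigma": self.noise_sigma,
            "gain": self.gain,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanRecord":
        d = json.loads(Path(path).read_text())
        return cls(
            measured_rows=np.asarray(d["measured_rows"], dtype=np.int64),
            bucket=np.asarray(d["bucket"], dtype=float),
            noise_sigma=d["noise_sigma"],
            gain=d["gain"],
            seed=d["seed"],
        )


def _acquire(
    scene: ThermalScene,
    S: SMatrix,
    rows: np.ndarray,
    noise_sigma: float,
    gain: float,
    seed: int | None,
) -> ScanRecord:
    if scene.shape != (S.p, S.q):
        raise ValueError(f"scene shape {scene.shape} != pattern shape ({S.p}, {S.q})")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    x = scene.radiance.ravel()  # row-major flattening, x_v = x(k, l), v = q*k + l
    y = gain * (S.matrix[rows] @ x)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=y.shape)
    return ScanRecord(
        measured_rows=np.asarray(rows, dtype=np.int64),
        bucket=y.astype(float),
        noise_sigma=noise_sigma,
        gain=gain,
        seed=seed,
    )


def simulate_scan(
    scene: ThermalScene,
    S: SMatrix,
    scheme: CodingScheme,
    noise_sigma: float = 0.0,
    gain: float = 1.0,
    seed: int | None = None,
) -> ScanRecord:
    """Acquire the scheme's m diagonal bucket signals from a scene.

    bucket_k = gain * <row u_k of S, flatten(scene)> + Normal(0, noise_sigma^2).
    """
    if (scheme.p, scheme.q) != (S.p, S.q):
        raise ValueError("scheme and S-matrix disagree on (p, q)")
    return _acquire(scene, S, scheme.measured_rows, noise_sigma, gain, seed)


def simulate_full_scan(
    scene: ThermalScene,
    S: SMatrix,
    noise_sigma: float = 0.0,
    gain: float = 1.0,
    seed: int | None = None,
) -> ScanRecord:
    """Uncompressed reference scan: all n rows in diagonal order (m = n)."""
    rows = diagonal_scan_rows(S.p, S.q, S.n)
    return _acquire(scene, S, rows, noise_sigma, gain, seed)
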