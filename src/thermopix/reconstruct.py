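"""Laplace interpolation of unmeasured bucket signals and closed-form recovery.

Adjacent measurement rows of a cyclic S-matrix are circular shifts of each
other, so bucket signals are smooth in linear index when the n-element
signal vector is reshaped row-major onto the p x q grid: the neighbors of
``y_u`` after reshaping are ``y_{u±1}`` and ``y_{u±q}``, all indices modulo
n.  Unmeasured signals are filled by discrete Laplace interpolation —

    y_u = (y_{u+1} + y_{u-1} + y_{u+q} + y_{u-q}) / 4

at every unmeasured u — i.e. the discrete harmonic extension of the
measured values on the modular 4-neighbor graph.  The coupled system is
solved exactly as a sparse linear system.  The image then follows in closed
form from the S-matrix inverse, x = 2/(n+1) (2 S^T y - sum(y) 1): no
iterative compressed-sensing solver is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .forward import ScanRecord
from .masks import CodingScheme, split_pattern
from .smatrix import SMatrix

__all__ = [
    "InterpolatedSignals",
    "ReconstructedImage",
    "laplace_interpolate",
    "reconstruct",
    "reassemble_fov",
]


@dataclass(frozen=True)
class InterpolatedSignals:
    """Complete n-element signal vector with the measured-position mask."""

    values: np.ndarray
    measured_mask: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ReconstructedImage:
    """Recovered p x q intensity grid with acquisition provenance."""

    grid: np.ndarray
    measured_rows: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def _neighbor_offsets(n: int, q: int) -> tuple[int, int, int, int]:
    return (1, n - 1, q, n - q)


def laplace_interpolate(record: ScanRecord, scheme: CodingScheme) -> InterpolatedSignals:
    """Fill unmeasured bucket signals by discrete Laplace interpolation.

    Every unmeasured index u satisfies
    ``y_u = (y_{u+1} + y_{u-1} + y_{u+q} + y_{u-q}) / 4`` exactly, with
    neighbor indices reduced modulo n; measured values pass through
    unchanged.  Unknowns may neighbor unknowns, so the coupled sparse
    system is assembled over all unmeasured sites and solved directly.
    The modular neighbor graph is connected, so the system is uniquely
    solvable whenever at least one signal was measured.
    """
    n = scheme.n
    rows = np.asarray(record.measured_rows, dtype=np.int64)
    if record.m == 0:
        raise ValueError("cannot interpolate from an empty scan")
    if len(np.unique(rows)) != len(rows):
        raise ValueError("measured rows must be distinct")
    if rows.min() < 0 or rows.max() >= n:
        raise ValueError("measured row index out of range")

    values = np.zeros(n, dtype=float)
    measured = np.zeros(n, dtype=bool)
    values[rows] = record.bucket
    measured[rows] = True

    unknown = np.flatnonzero(~measured)
    if unknown.size == 0:
        return InterpolatedSignals(values=values, measured_mask=measured)

    pos = -np.ones(n, dtype=np.int64)  # unknown index -> equation number
    pos[unknown] = np.arange(unknown.size)

    data, ri, ci = [], [], []
    rhs = np.zeros(unknown.size, dtype=float)
    for eq, u in enumerate(unknown):
        data.append(4.0)
        ri.append(eq)
        ci.append(eq)
        for off in _neighbor_offsets(n, scheme.q):
            v = (u + off) % n
            if measured[v]:
                rhs[eq] += values[v]
            else:
                data.append(-1.0)
                ri.append(eq)
                ci.append(pos[v])
    A = sp.csr_matrix((data, (ri, ci)), shape=(unknown.size, unknown.size))
    values[unknown] = spsolve(A, rhs)
    return InterpolatedSignals(values=values, measured_mask=measured)


def gauss_seidel_interpolate(
    record: ScanRecord,
    scheme: CodingScheme,
    tol: float = 1e-10,
    max_sweeps: int = 100_000,
) -> InterpolatedSignals:
    """Fixed-point reference for :func:`laplace_interpolate` (slow; exact
    solve is the production path)."""
    n = scheme.n
    rows = np.asarray(record.measured_rows, dtype=np.int64)
    values = np.zeros(n, dtype=float)
    measured = np.zeros(n, dtype=bool)
    values[rows] = record.bucket
    measured[rows] = True
    values[~measured] = values[measured].mean()
    unknown = np.flatnonzero(~measured)
    offs = _neighbor_offsets(n, scheme.q)
    for _ in range(max_sweeps):
        delta = 0.0
        for u in unknown:
            new = sum(values[(u + off) % n] for off in offs) / 4.0
            delta = max(delta, abs(new - values[u]))
            values[u] = new
        if delta < tol:
            break
    return InterpolatedSignals(values=values, measured_mask=measured)


def reconstruct(
    y_tilde: InterpolatedSignals | np.ndarray, S: SMatrix
) -> ReconstructedImage:
    """Recover the image by the closed-form S-matrix inverse.

    ``x = 2/(n+1) * (2 S^T y - sum(y))``, reshaped row-major to (p, q).
    Cost is one matrix-vector product, O(n^2); no iteration.
    """
    if isinstance(y_tilde, InterpolatedSignals):
        y = y_tilde.values
        rows = np.flatnonzero(y_tilde.measured_mask)
    else:
        y = np.asarray(y_tilde, dtype=float)
        rows = None
    if len(y) != S.n:
        raise ValueError(f"signal length {len(y)} != matrix order {S.n}")
    x = (2.0 / (S.n + 1)) * (2.0 * (S.matrix.T @ y) - y.sum())
    return ReconstructedImage(grid=x.reshape(S.p, S.q), measured_rows=rows)


def reassemble_fov(
    img: ReconstructedImage, scheme: CodingScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Split a reconstructed grid into the two FOV window regions.

    Applies the split-window geometry (widths (q+1)/2 and (q-1)/2, plus the
    configured flips) to the reconstruction, yielding the images for the
    left (-45 deg rotated) and right (+45 deg rotated) windows.  The
    rotation is display metadata only; pixel values are untouched.
    """
    return split_pattern(img.grid, scheme)
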