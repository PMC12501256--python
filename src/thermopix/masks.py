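"""2D encoding patterns, diagonal compressed scanning, and the physical stripe.

A row of the cyclic S-matrix, reshaped row-major to a ``p x q`` grid, is one
encoding pattern.  Tiling the first row over an extended grid produces a
matrix ``T(a, b) = S[0, (q*a + b) mod n]`` in which the pattern of row
``(q+1)*k mod n`` appears as the crop ``T[k:k+p, k:k+q]``: stepping one cell
down the diagonal advances the measurement row by ``q + 1`` in linear index,
i.e. by (1, 1) in 2D bucket-signal coordinates.  A single stripe of masks
scanned continuously therefore acquires the bucket signals ``y(0,0),
y(1,1), ..., y(m-1,m-1)`` — a diagonal compressed scan whose samples are
nearly uniformly spread over the 2D-reshaped signal array.

Because gcd(q+1, n) = 1 for twin primes (q+1 = p+3 shares no factor with
p*q), the diagonal scan visits all n rows before repeating.

Each pattern is also split into two window parts of widths (q+1)/2 and
(q-1)/2 columns — matching the two open windows placed over the left and
right inner canthi — with optional per-part flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .smatrix import SMatrix

__all__ = [
    "CodingScheme",
    "EncodingPattern",
    "StripeLayout",
    "pattern_for_row",
    "tiled_matrix",
    "diagonal_scan_rows",
    "aggregate_stripe",
    "split_pattern",
    "reassemble_pattern",
]

#: physical defaults: 250 um encoding pixels, 4:1 demagnification onto the
#: mask plane, 7.5 mm stripe separation on the mask plate
DEFAULT_PIXEL_PITCH_MM = 0.25
DEFAULT_MAGNIFICATION = 4.0
DEFAULT_STRIPE_SEPARATION_MM = 7.5


@dataclass(frozen=True)
class FlipConfig:
    """Horizontal/vertical flip flags applied to each split window part."""

    part_a_fliplr: bool = False
    part_a_flipud: bool = False
    part_b_fliplr: bool = False
    part_b_flipud: bool = False


@dataclass(frozen=True)
class CodingScheme:
    """Geometry of a compressed diagonal scan.

    Parameters
    ----------
    p, q : int
        Twin primes defining the pattern shape (p rows, q columns).
    m : int
        Scan length, the number of bucket signals acquired (m <= n).
    flip_config : FlipConfig
        Per-part flips applied when splitting patterns into window parts.
    pixel_pitch_mm : float
        Physical encoding-pixel size at the mask plane.
    magnification : float
        Object-to-mask magnification ratio.
    stripe_separation_mm : float
        Distance between the two encoded stripes on the mask plate.
    """

    p: int
    q: int
    m: int
    flip_config: FlipConfig = field(default_factory=FlipConfig)
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    magnification: float = DEFAULT_MAGNIFICATION
    stripe_separation_mm: float = DEFAULT_STRIPE_SEPARATION_MM

    def __post_init__(self) -> None:
        if self.m < 1 or self.m > self.n:
            raise ValueError(f"scan length m={self.m} must satisfy 1 <= m <= n={self.n}")

    @property
    def n(self) -> int:
        return self.p * self.q

    @property
    def measured_rows(self) -> np.ndarray:
        return diagonal_scan_rows(self.p, self.q, self.m)

    @property
    def split_widths(self) -> tuple[int, int]:
        return (self.q + 1) // 2, (self.q - 1) // 2

    @property
    def object_pixel_size_mm(self) -> float:
        """Area sampled by one encoding pixel in the object plane."""
        return self.pixel_pitch_mm * self.magnification

    @property
    def object_region_separation_mm(self) -> float:
        """Separation of the two FOV regions in the object plane."""
        return self.stripe_separation_mm * self.magnification


@dataclass(frozen=True)
class EncodingPattern:
    """One p x q binary encoding pattern: row ``row_index`` of S, reshaped."""

    row_index: int
    grid: np.ndarray


def pattern_for_row(S: SMatrix, u: int) -> EncodingPattern:
    """Row ``u`` of the S-matrix reshaped row-major to a p x q grid."""
    if not 0 <= u < S.n:
        raise IndexError(f"row index {u} out of range [0, {S.n})")
    return EncodingPattern(row_index=u, grid=S.matrix[u].reshape(S.p, S.q).copy())


def tiled_matrix(S: SMatrix, rows: int, cols: int) -> np.ndarray:
    """Tile the first row over an extended grid: T(a,b) = S[0, (q*a+b) mod n].

    The crop ``T[k:k+p, k:k+q]`` equals the encoding pattern of measurement
    row ``(q+1)*k mod n``, which is what makes a continuous diagonal scan of
    a single physical stripe step through the compressed measurement rows.
    """
    if rows < S.p or cols < S.q:
        raise ValueError(f"extent ({rows}, {cols}) smaller than pattern ({S.p}, {S.q})")
    a = np.arange(rows)[:, None]
    b = np.arange(cols)[None, :]
    return S.first_row[(S.q * a + b) % S.n]


def diagonal_scan_rows(p: int, q: int, m: int) -> np.ndarray:
    """Measurement rows of the diagonal compressed scan: u_k = (q+1)*k mod n.

    The offset q+1 is the linear index of a (1, 1) shift in the 2D
    bucket-signal array; since gcd(q+1, p*q) = 1 the m rows are distinct
    for every m <= n.
    """
    n = p * q
    if m < 1 or m > n:
        raise ValueError(f"m={m} must satisfy 1 <= m <= n={n}")
    return ((q + 1) * np.arange(m, dtype=np.int64)) % n


@dataclass(frozen=True)
class StripeLayout:
    """The physically aggregated mask stripe plus fabrication markers.

    ``band`` is the transmission raster (1 = open); ``opaque_mask`` marks
    cells outside the diagonal band (always opaque, not part of any
    pattern).  ``runway_markers`` and ``alignment_pixels`` record the
    fabrication-aid geometry; they never enter the measurement matrix.
    """

    band: np.ndarray
    opaque_mask: np.ndarray
    measured_rows: np.ndarray
    p: int
    q: int
    runway_markers: tuple[tuple[int, int], ...] = ()
    alignment_pixels: tuple[tuple[int, int], ...] = ()

    def crop(self, k: int) -> np.ndarray:
        """Extract the p x q pattern at diagonal position k."""
        if not 0 <= k < len(self.measured_rows):
            raise IndexError(f"position {k} out of range")
        return self.band[k : k + self.p, k : k + self.q]


def aggregate_stripe(S: SMatrix, m: int, runway: bool = False, runway_size: int = 3) -> StripeLayout:
    """Union of the m diagonal crops of the tiled matrix into one stripe.

    Crop-extraction of position k reproduces ``pattern_for_row(S, (q+1)k mod
    n)`` exactly.  With ``runway`` on, four L-shaped run-way patterns (size
    ``runway_size``) are appended at both ends of the stripe and one
    alignment pixel is placed at the same horizontal position on the top and
    bottom; markers live in metadata only.
    """
    rows_idx = diagonal_scan_rows(S.p, S.q, m)
    height = (m - 1) + S.p
    width = (m - 1) + S.q
    T = tiled_matrix(S, height, width)

    inside = np.zeros((height, width), dtype=bool)
    for k in range(m):
        inside[k : k + S.p, k : k + S.q] = True

    band = np.where(inside, T, 0)
    layout = StripeLayout(
        band=band,
        opaque_mask=~inside,
        measured_rows=rows_idx,
        p=S.p,
        q=S.q,
    )
    if not runway:
        return layout

    # L-shaped run-ways flank the band at both ends (two per end, one on each
    # side of the diagonal); anchors are recorded as top-left corners in
    # stripe coordinates extended by runway_size on every side.
    r = runway_size
    markers = (
        (-r, -r),
        (-r, S.q),
        (height, width - S.q - r),
        (height, width + r - r),
    )
    mid_col = width // 2
    align = ((-r - 1, mid_col), (height + r, mid_col))
    return StripeLayout(
        band=band,
        opaque_mask=~inside,
        measured_rows=rows_idx,
        p=S.p,
        q=S.q,
        runway_markers=markers,
        alignment_pixels=align,
    )


def _apply_flips(part: np.ndarray, fliplr: bool, flipud: bool) -> np.ndarray:
    if fliplr:
        part = np.fliplr(part)
    if flipud:
        part = np.flipud(part)
    return part


def split_pattern(grid: np.ndarray, scheme: CodingScheme) -> tuple[np.ndarray, np.ndarray]:
    """Split a p x q pattern into window parts of widths (q+1)/2 and (q-1)/2.

    Part A takes the first (q+1)/2 columns, part B the rest; each part is
    then flipped per the scheme's flip_config.  ``reassemble_pattern``
    inverts the operation exactly.
    """
    grid = np.asarray(grid)
    if grid.shape != (scheme.p, scheme.q):
        raise ValueError(f"pattern shape {grid.shape} != ({scheme.p}, {scheme.q})")
    wa, _ = scheme.split_widths
    fc = scheme.flip_config
    part_a = _apply_flips(grid[:, :wa].copy(), fc.part_a_fliplr, fc.part_a_flipud)
    part_b = _apply_flips(grid[:, wa:].copy(), fc.part_b_fliplr, fc.part_b_flipud)
    return part_a, part_b


def reassemble_pattern(part_a: np.ndarray, part_b: np.ndarray, scheme: CodingScheme) -> np.ndarray:
    """Exact inverse of :func:`split_pattern`, including flips."""
    wa, wb = scheme.split_widths
    part_a, part_b = np.asarray(part_a), np.asarray(part_b)
    if part_a.shape != (scheme.p, wa) or part_b.shape != (scheme.p, wb):
        raise ValueError(
            f"part shapes {part_a.shape}, {part_b.shape} incompatible with "
            f"({scheme.p}, {wa}) and ({scheme.p}, {wb})"
        )
    fc = scheme.flip_config
    # flips are involutions: undo by re-applying
    a = _apply_flips(part_a, fc.part_a_fliplr, fc.part_a_flipud)
    b = _apply_flips(part_b, fc.part_b_fliplr, fc.part_b_flipud)
    return np.concatenate([a, b], axis=1)
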