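"""Synthetic thermal scenes: uniform fields, letter plates, slits, canthi.

These phantoms emulate the bench targets used to characterize the imager:
a spatially uniform blackbody field, metal plates with engraved dot-matrix
letters at a different temperature than the field behind them, a narrow
slit (down to half an encoding pixel wide) rotated to 0, 90, +/-45 degrees
for spatial-resolution measurement, and a pair of inner-canthi-like hot
spots on a skin-temperature background.

Sub-pixel features are rasterized by area-weighted coverage of each
encoding pixel: exactly for axis-aligned rectangles, by 16x16 supersampling
for rotated slits.  Temperatures convert to radiance through a calibration
model so that phantom -> scan -> reconstruct -> temperature map round trips
are self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import ThermalScene
from .masks import CodingScheme
from .radiometry import CalibrationModel, celsius_to_kelvin

__all__ = ["PhantomSpec", "make_phantom", "letter_mask", "slit_coverage"]

PHANTOM_KINDS = ("uniform", "letter", "slit", "canthi", "two_level")

# 5x7 dot-matrix glyphs (row-major strings, '#' = stroke).  X is symmetric
# under 180-degree rotation, as the physical engraving was.
_FONT_5x7: dict[str, tuple[str, ...]] = {
    "X": (
        "#...#",
        "#...#",
        ".#.#.",
        "..#..",
        ".#.#.",
        "#...#",
        "#...#",
    ),
    "Z": (
        "#####",
        "....#",
        "...#.",
        "..#..",
        ".#...",
        "#....",
        "#####",
    ),
    "H": (
        "#...#",
        "#...#",
        "#...#",
        "#####",
        "#...#",
        "#...#",
        "#...#",
    ),
    "I": (
        "#####",
        "..#..",
        "..#..",
        "..#..",
        "..#..",
        "..#..",
        "#####",
    ),
    "L": (
        "#....",
        "#....",
        "#....",
        "#....",
        "#....",
        "#....",
        "#####",
    ),
    "O": (
        ".###.",
        "#...#",
        "#...#",
        "#...#",
        "#...#",
        "#...#",
        ".###.",
    ),
    "T": (
        "#####",
        "..#..",
        "..#..",
        "..#..",
        "..#..",
        "..#..",
        "..#..",
    ),
    "U": (
        "#...#",
        "#...#",
        "#...#",
        "#...#",
        "#...#",
        "#...#",
        ".###.",
    ),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic thermal scene.

    Parameters
    ----------
    kind : one of {uniform, letter, slit, canthi, two_level}
    temperature_C : feature temperature in deg C (the uniform field value
        for kind "uniform").
    background_C : background temperature in deg C (ignored for uniform).
    glyph : letter for kind "letter".
    slit_width_px : slit width in encoding pixels (0.5 reproduces the
        half-pixel resolution target).
    slit_angle_deg : one of {0, 90, 45, -45}; 0 = vertical slit (profile
        taken along the horizontal axis).
    slit_offset_px : signed shift of the slit center from the grid center,
        measured across the slit.
    spot_centers / spot_sigma_px : hot-spot centers (row, col) and Gaussian
        width for kind "canthi"; defaults place two spots side by side.
    hot_region : explicit boolean mask for kind "two_level".
    """

    kind: str
    temperature_C: float = 37.0
    background_C: float = 22.0
    glyph: str = "X"
    slit_width_px: float = 0.5
    slit_angle_deg: float = 0.0
    slit_offset_px: float = 0.0
    spot_centers: tuple[tuple[float, float], ...] = ()
    spot_sigma_px: float = 1.2
    hot_region: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {PHANTOM_KINDS}")
        if self.temperature_C <= -273.15 or self.background_C <= -273.15:
            raise ValueError("temperatures must exceed absolute zero")


def letter_mask(glyph: str, scheme: CodingScheme) -> np.ndarray:
    """Boolean p x q raster of a 5x7 dot-matrix glyph, centered.

    Raises for glyphs outside the supported set or grids smaller than the
    glyph.
    """
    if glyph not in _FONT_5x7:
        raise ValueError(f"unsupported glyph {glyph!r}; supported: {sorted(_FONT_5x7)}")
    rows, cols = 7, 5
    if scheme.p < rows or scheme.q < cols:
        raise ValueError(f"grid ({scheme.p}, {scheme.q}) smaller than glyph ({rows}, {cols})")
    mask = np.zeros((scheme.p, scheme.q), dtype=bool)
    r0 = (scheme.p - rows) // 2
    c0 = (scheme.q - cols) // 2
    for r, line in enumerate(_FONT_5x7[glyph]):
        for c, ch in enumerate(line):
            if ch == "#":
                mask[r0 + r, c0 + c] = True
    return mask


def slit_coverage(
    p: int,
    q: int,
    width_px: float,
    angle_deg: float,
    offset_px: float = 0.0,
    supersample: int = 16,
) -> np.ndarray:
    """Fractional pixel coverage of a slit through the grid center.

    The slit is an infinite band of the given width whose axis passes
    through the grid center (shifted by ``offset_px`` across the slit),
    rotated by ``angle_deg`` from vertical.  Axis-aligned angles use the
    exact interval-overlap area; rotated slits are supersampled.
    """
    if width_px <= 0:
        raise ValueError("slit width must be positive")
    cy, cx = p / 2.0, q / 2.0
    half = width_px / 2.0

    if angle_deg % 90 == 0:
        # distance across the slit is a single coordinate: exact overlap of
        # [pixel] with [center - half, center + half]
        horizontal = (angle_deg % 180) == 90  # slit axis horizontal -> varies in y
        extent = p if horizontal else q
        center = (cy if horizontal else cx) + offset_px
        lo, hi = center - half, center + half
        edges = np.arange(extent + 1, dtype=float)
        overlap = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, 1.0)
        cov = np.tile(overlap[:, None], (1, q)) if horizontal else np.tile(overlap[None, :], (p, 1))
        return cov

    theta = np.deg2rad(angle_deg)
    # unit normal across the slit (slit axis at angle_deg from vertical)
    nrm = np.array([np.sin(theta), np.cos(theta)])  # (d_col, d_row) ordering below
    s = supersample
    sub = (np.arange(s) + 0.5) / s
    yy = np.add.outer(np.arange(p), sub).reshape(p, 1, s, 1)
    xx = np.add.outer(np.arange(q), sub).reshape(1, q, 1, s)
    dist = (xx - cx - offset_px * nrm[0]) * nrm[0] + (yy - cy - offset_px * nrm[1]) * nrm[1]
    inside = np.abs(dist) <= half
    return inside.mean(axis=(2, 3))


def _canthi_field(spec: PhantomSpec, scheme: CodingScheme) -> np.ndarray:
    centers = spec.spot_centers
    if not centers:
        # one hot spot per window region, mid-height
        wa, _ = scheme.split_widths
        centers = (
            (scheme.p / 2.0, wa / 2.0),
            (scheme.p / 2.0, wa + (scheme.q - wa) / 2.0),
        )
    yy, xx = np.mgrid[0 : scheme.p, 0 : scheme.q]
    w = np.zeros((scheme.p, scheme.q))
    for (r, c) in centers:
        if not (0 <= r <= scheme.p and 0 <= c <= scheme.q):
            raise ValueError(f"hot-spot center {(r, c)} outside grid")
        w = np.maximum(
            w,
            np.exp(-(((yy + 0.5 - r) ** 2 + (xx + 0.5 - c) ** 2) / (2 * spec.spot_sigma_px**2))),
        )
    return w


def make_phantom(
    spec: PhantomSpec,
    scheme: CodingScheme,
    calibration: CalibrationModel | None = None,
) -> ThermalScene:
    """Rasterize a phantom spec to a radiance scene on the scheme's grid.

    Feature/background temperatures are mixed by fractional pixel coverage
    (area-weighted, in radiance space) and converted to radiance through
    the calibration model (a unit-gain, zero-offset model by default).
    """
    shape = (scheme.p, scheme.q)
    model = calibration or CalibrationModel.uniform(shape)
    if model.shape != shape:
        raise ValueError("calibration model shape mismatch")

    T_hot = celsius_to_kelvin(spec.temperature_C)
    T_bg = celsius_to_kelvin(spec.background_C)

    if spec.kind == "uniform":
        coverage = np.ones(shape)
        T_bg = T_hot
    elif spec.kind == "letter":
        coverage = letter_mask(spec.glyph, scheme).astype(float)
    elif spec.kind == "slit":
        if spec.slit_angle_deg not in (0.0, 90.0, 45.0, -45.0):
            raise ValueError("slit angle must be one of 0, 90, 45, -45 degrees")
        coverage = slit_coverage(
            scheme.p, scheme.q, spec.slit_width_px, spec.slit_angle_deg, spec.slit_offset_px
        )
    elif spec.kind == "canthi":
        coverage = _canthi_field(spec, scheme)
    elif spec.kind == "two_level":
        if spec.hot_region is None:
            raise ValueError("two_level phantom requires hot_region mask")
        region = np.asarray(spec.hot_region, dtype=bool)
        if region.shape != shape:
            raise ValueError("hot_region shape mismatch")
        coverage = region.astype(float)
    else:  # pragma: no cover - guarded by PhantomSpec
        raise ValueError(spec.kind)

    rad_hot = model.radiance(T_hot)
    rad_bg = model.radiance(T_bg)
    radiance = coverage * rad_hot + (1.0 - coverage) * rad_bg
    # effective temperature per pixel (inverse of the model; for display)
    eff_T4 = coverage * T_hot**4 + (1.0 - coverage) * T_bg**4
    return ThermalScene(radiance=radiance, temperature_K=eff_T4**0.25)
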