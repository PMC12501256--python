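"""Radiometric calibration and intensity-to-temperature conversion.

The reconstructed intensity of a pixel viewing a blackbody-like source at
absolute temperature T_s follows the total-radiance (Stefan-Boltzmann)
model

    x = C * eps * sigma * T_s^4 + Delta,

where eps is the emissivity (0.98 for both the calibration blackbody and
human skin), sigma = 5.670e-8 W m^-2 K^-4, C is a per-pixel gain absorbing
emission area and light-to-voltage conversion, and Delta a per-pixel
offset.  C and Delta are determined by pixel-by-pixel ordinary least
squares over a sweep of preset blackbody temperatures.  The measured
temperature map inverts the model,

    T_m = ((x - Delta) / (C * eps * sigma))^(1/4),

subtracting the fitted offset before the fourth root — the algebraic
inverse of the calibration model (the offset-free variant would bias every
reading whenever Delta != 0).  All internal temperatures are kelvin;
degrees Celsius appear only at interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruct import ReconstructedImage

__all__ = [
    "STEFAN_BOLTZMANN",
    "DEFAULT_EMISSIVITY",
    "FEVER_THRESHOLD_C",
    "CalibrationModel",
    "TemperatureMap",
    "fit_calibration",
    "temperature_map",
    "region_mean_temperature",
    "temperature_resolution",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

STEFAN_BOLTZMANN = 5.67e-8  # W m^-2 K^-4
DEFAULT_EMISSIVITY = 0.98  # blackbody source and human skin
#: recommended inner-canthus screening threshold for fever
FEVER_THRESHOLD_C = 37.1


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + 273.15


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - 273.15


@dataclass(frozen=True)
class CalibrationModel:
    """Per-pixel gain/offset of the T^4 radiance model.

    Attributes
    ----------
    C : ndarray (p, q)
        Per-pixel gain, intensity per W m^-2; positive after a good fit.
    Delta : ndarray (p, q)
        Per-pixel offset in intensity units.
    emissivity : float
    sigma_SB : float
    fit_residuals : ndarray (p, q) or None
        Per-pixel RMS of the fit residuals.
    valid : ndarray (p, q) of bool
        False where the fitted gain is non-positive.
    """

    C: np.ndarray
    Delta: np.ndarray
    emissivity: float = DEFAULT_EMISSIVITY
    sigma_SB: float = STEFAN_BOLTZMANN
    fit_residuals: np.ndarray | None = None
    valid: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.C.shape

    def radiance(self, T_s_kelvin) -> np.ndarray:
        """Forward model: C * eps * sigma * T_s^4 + Delta."""
        T = np.asarray(T_s_kelvin, dtype=float)
        return self.C * self.emissivity * self.sigma_SB * T**4 + self.Delta

    @classmethod
    def uniform(
        cls,
        shape: tuple[int, int],
        C: float = 1.0,
        Delta: float = 0.0,
        emissivity: float = DEFAULT_EMISSIVITY,
    ) -> "CalibrationModel":
        """Spatially uniform model, handy for phantom generation."""
        return cls(
            C=np.full(shape, float(C)),
            Delta=np.full(shape, float(Delta)),
            emissivity=emissivity,
            valid=np.full(shape, C > 0),
        )


@dataclass(frozen=True)
class TemperatureMap:
    """Measured temperature grid (kelvin) with a validity mask.

    Pixels where the inversion radicand (x - Delta)/C was non-positive are
    flagged invalid; a zero radicand maps to 0 K and is flagged as an
    invalid boundary case.
    """

    T_kelvin: np.ndarray
    valid: np.ndarray

    @property
    def T_celsius(self) -> np.ndarray:
        return kelvin_to_celsius(self.T_kelvin)


def fit_calibration(
    frames: list[ReconstructedImage | np.ndarray],
    preset_temps_K: np.ndarray,
    emissivity: float = DEFAULT_EMISSIVITY,
    sigma_SB: float = STEFAN_BOLTZMANN,
) -> CalibrationModel:
    """Pixel-by-pixel linear fit of intensity against eps*sigma*T_s^4.

    Parameters
    ----------
    frames : list of reconstructed frames, one per entry of preset_temps_K
        Replicates are passed as repeated temperature entries.
    preset_temps_K : array of kelvin temperatures, same length as frames.

    Returns
    -------
    CalibrationModel with per-pixel slope C, intercept Delta and residual
    RMS.  Pixels with non-positive fitted C are flagged, not raised.
    """
    T = np.asarray(preset_temps_K, dtype=float)
    if len(frames) != len(T):
        raise ValueError("one preset temperature per frame required")
    if len(np.unique(T)) < 2:
        raise ValueError("calibration needs at least 2 distinct preset temperatures")

    grids = np.stack(
        [f.grid if isinstance(f, ReconstructedImage) else np.asarray(f, dtype=float) for f in frames]
    )  # (n_frames, p, q)
    shape = grids.shape[1:]

    # regressor is the blackbody radiance eps*sigma*T^4; one shared design
    # matrix, solved for all pixels at once
    r = emissivity * sigma_SB * T**4
    A = np.column_stack([r, np.ones_like(r)])
    B = grids.reshape(len(T), -1)
    coef, *_ = np.linalg.lstsq(A, B, rcond=None)
    C = coef[0].reshape(shape)
    Delta = coef[1].reshape(shape)
    resid = (A @ coef - B).reshape(len(T), *shape)
    rms = np.sqrt((resid**2).mean(axis=0))
    return CalibrationModel(
        C=C,
        Delta=Delta,
        emissivity=emissivity,
        sigma_SB=sigma_SB,
        fit_residuals=rms,
        valid=C > 0,
    )


def temperature_map(
    img: ReconstructedImage | np.ndarray, model: CalibrationModel
) -> TemperatureMap:
    """Invert the calibration model: T = ((x - Delta)/(C eps sigma))^(1/4).

    The fitted offset is subtracted before the fourth root.  Pixels where
    the radicand is negative (or the fitted gain non-positive) are masked
    invalid; exact zeros yield 0 K flagged invalid.
    """
    x = img.grid if isinstance(img, ReconstructedImage) else np.asarray(img, dtype=float)
    if x.shape != model.shape:
        raise ValueError(f"image shape {x.shape} != calibration shape {model.shape}")
    gain_ok = model.C > 0 if model.valid is None else model.valid
    denom = model.C * model.emissivity * model.sigma_SB
    with np.errstate(divide="ignore", invalid="ignore"):
        radicand = np.where(gain_ok, (x - model.Delta) / denom, np.nan)
    valid = gain_ok & (radicand > 0)
    T = np.where(valid, np.clip(radicand, 0, None) ** 0.25, 0.0)
    return TemperatureMap(T_kelvin=T, valid=valid)


def region_mean_temperature(
    tmap: TemperatureMap, region: np.ndarray
) -> tuple[float, float]:
    """Mean and SD (deg C) over the valid pixels of a region mask.

    This is the statistic read out over each inner canthus; a region mean
    at or above 37.1 deg C flags fever-positive screening.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != tmap.T_kelvin.shape:
        raise ValueError("region mask shape mismatch")
    sel = region & tmap.valid
    if not sel.any():
        raise ValueError("region contains no valid pixels")
    vals = tmap.T_celsius[sel]
    return float(vals.mean()), float(vals.std())


def temperature_resolution(
    samples_by_level: dict[float, np.ndarray],
) -> tuple[float, float]:
    """Resolution estimate from a ladder of repeated measurements.

    Two definitions are reported (both are conventions of this package):

    - the smallest preset-temperature step at which the interquartile boxes
      of adjacent levels do not overlap (deg C), and
    - the RMS error of all recovered samples about their preset levels.

    ``samples_by_level`` maps each preset temperature (deg C) to the pooled
    recovered per-pixel temperatures (deg C) at that setting.
    """
    levels = sorted(samples_by_level)
    if len(levels) < 2:
        raise ValueError("need at least two temperature levels")
    resolvable_steps = []
    for lo, hi in zip(levels, levels[1:]):
        q_lo = np.percentile(samples_by_level[lo], [25, 75])
        q_hi = np.percentile(samples_by_level[hi], [25, 75])
        if q_lo[1] < q_hi[0]:  # boxes disjoint: step resolved
            resolvable_steps.append(hi - lo)
    iqr_resolution = float(min(resolvable_steps)) if resolvable_steps else float("inf")
    sq = [
        np.mean((np.asarray(samples_by_level[lv]) - lv) ** 2)
        for lv in levels
    ]
    rms_error = float(np.sqrt(np.mean(sq)))
    return iqr_resolution, rms_error
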