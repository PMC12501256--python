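"""Radiometric calibration fitting and temperature-map inversion."""

import numpy as np
import pytest

from thermopix import (
    CalibrationModel,
    CodingScheme,
    PhantomSpec,
    celsius_to_kelvin,
    fit_calibration,
    make_phantom,
    region_mean_temperature,
    simulate_calibration_sweep,
    simulate_scan,
    temperature_map,
    temperature_resolution,
)
from thermopix.pipeline import calibration_sweep_temps_C
from thermopix.radiometry import FEVER_THRESHOLD_C, STEFAN_BOLTZMANN


@pytest.fixture(scope="module")
def true_model(rng_=np.random.default_rng(99)):
    # per-pixel gain/offset with realistic spatial variation
    C = 1.0 + 0.2 * rng_.uniform(-1, 1, (11, 13))
    Delta = 5.0 * rng_.uniform(-1, 1, (11, 13))
    return CalibrationModel(C=C, Delta=Delta, valid=C > 0)


def _sweep_frames(model, temps_C, replicates=1):
    frames, temps_K = [], []
    for t in temps_C:
        for _ in range(replicates):
            frames.append(model.radiance(celsius_to_kelvin(t)))
            temps_K.append(float(celsius_to_kelvin(t)))
    return frames, np.asarray(temps_K)


class TestFitCalibration:
    def test_exact_recovery_on_noiseless_sweep(self, true_model):
        # the sweep: 31.7 to 39.8 deg C in 0.9 deg C steps
        temps = calibration_sweep_temps_C()
        assert temps[0] == pytest.approx(31.7) and temps[-1] == pytest.approx(39.8)
        frames, temps_K = _sweep_frames(true_model, temps)
        fit = fit_calibration(frames, temps_K)
        assert np.abs(fit.C / true_model.C - 1).max() < 1e-9
        assert np.abs(fit.Delta - true_model.Delta).max() < 1e-6
        assert fit.valid.all()

    def test_replicate_sample_count(self):
        # 5 replicate frames of 143 pixels give 715 per-pixel samples at
        # each temperature level
        model = CalibrationModel.uniform((11, 13))
        frames, temps_K = _sweep_frames(model, calibration_sweep_temps_C(), replicates=5)
        level = temps_K == temps_K[0]
        samples_per_level = int(level.sum()) * frames[0].size
        assert samples_per_level == 715

    def test_single_temperature_rejected(self, true_model):
        frames, temps_K = _sweep_frames(true_model, [37.0, 37.0, 37.0])
        with pytest.raises(ValueError):
            fit_calibration(frames, temps_K)

    def test_residuals_near_zero_noiseless(self, true_model):
        frames, temps_K = _sweep_frames(true_model, calibration_sweep_temps_C())
        fit = fit_calibration(frames, temps_K)
        assert fit.fit_residuals.max() < 1e-8


class TestTemperatureMap:
    def test_round_trip_uniform_37C(self, S143, scheme_full):
        # 37.0 deg C scene -> noiseless scan -> reconstruct -> map
        scheme = scheme_full
        model = CalibrationModel.uniform((11, 13))
        scene = make_phantom(PhantomSpec(kind="uniform", temperature_C=37.0), scheme, model)
        from thermopix import laplace_interpolate, reconstruct, simulate_full_scan

        rec = simulate_full_scan(scene, S143)
        img = reconstruct(laplace_interpolate(rec, scheme), S143)
        tmap = temperature_map(img, model)
        assert tmap.valid.all()
        assert np.abs(tmap.T_celsius - 37.0).max() < 1e-6

    def test_forward_inverse_identity_any_temperature(self, true_model):
        for t_c in (0.5, 20.0, 36.6, 41.0, 100.0):
            x = true_model.radiance(celsius_to_kelvin(t_c))
            tmap = temperature_map(x, true_model)
            assert np.abs(tmap.T_celsius - t_c).max() < 1e-9

    def test_intensity_equal_offset_maps_to_zero_kelvin_invalid(self, true_model):
        tmap = temperature_map(true_model.Delta.copy(), true_model)
        assert np.all(tmap.T_kelvin == 0.0)
        assert not tmap.valid.any()

    def test_monotone_in_intensity(self, true_model):
        x1 = true_model.radiance(celsius_to_kelvin(30.0))
        x2 = true_model.radiance(celsius_to_kelvin(30.1))
        t1 = temperature_map(x1, true_model).T_kelvin
        t2 = temperature_map(x2, true_model).T_kelvin
        assert np.all(t2 > t1)

    def test_nonpositive_gain_flagged(self):
        C = np.ones((3, 5))
        C[1, 2] = -1.0
        model = CalibrationModel(C=C, Delta=np.zeros((3, 5)), valid=C > 0)
        tmap = temperature_map(np.full((3, 5), 100.0), model)
        assert not tmap.valid[1, 2]
        assert tmap.valid.sum() == 14


class TestNoisyChain:
    def test_unbiased_and_noise_ladder(self, S143, scheme91):
        # recovered temperatures are unbiased, and their spread shrinks as
        # the bucket noise shrinks
        model = CalibrationModel.uniform((11, 13))
        spreads = []
        for sigma_frac in (2e-3, 5e-4):
            frames, temps_K = simulate_calibration_sweep(
                S143, scheme91, model, noise_sigma=sigma_frac * 72 * model.radiance(310.15)[0, 0],
                seed=11, replicates=5,
            )
            fit = fit_calibration([f.grid for f in frames], temps_K)
            scene = make_phantom(PhantomSpec(kind="uniform", temperature_C=37.0), scheme91, model)
            from thermopix import laplace_interpolate, reconstruct

            recovered = []
            for s in range(8):
                rec = simulate_scan(
                    scene, S143, scheme91,
                    noise_sigma=sigma_frac * 72 * scene.radiance[0, 0], seed=1000 + s,
                )
                img = reconstruct(laplace_interpolate(rec, scheme91), S143)
                recovered.append(temperature_map(img, fit).T_celsius)
            recovered = np.stack(recovered)
            bias = recovered.mean() - 37.0
            spreads.append(recovered.std())
            assert abs(bias) < 5 * recovered.std() / np.sqrt(recovered.size) + 0.05
        assert spreads[1] < spreads[0]


class TestRegionStatistics:
    def test_uniform_region_mean(self):
        model = CalibrationModel.uniform((11, 13))
        tmap = temperature_map(model.radiance(celsius_to_kelvin(37.0)), model)
        region = np.zeros((11, 13), dtype=bool)
        region[4:7, 2:5] = True
        mean, sd = region_mean_temperature(tmap, region)
        assert mean == pytest.approx(37.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_two_level_region_reads_hot_value(self):
        model = CalibrationModel.uniform((11, 13))
        T = np.full((11, 13), 30.0)
        T[:, :7] = 39.0
        tmap = temperature_map(model.radiance(celsius_to_kelvin(T)), model)
        hot = np.zeros((11, 13), dtype=bool)
        hot[:, :7] = True
        mean, _ = region_mean_temperature(tmap, hot)
        assert mean == pytest.approx(39.0, abs=1e-9)

    def test_fever_threshold_flag(self):
        model = CalibrationModel.uniform((11, 13))
        tmap = temperature_map(model.radiance(celsius_to_kelvin(37.4)), model)
        mean, _ = region_mean_temperature(tmap, np.ones((11, 13), dtype=bool))
        assert mean >= FEVER_THRESHOLD_C

    def test_empty_region_rejected(self):
        model = CalibrationModel.uniform((3, 5))
        tmap = temperature_map(model.radiance(310.0), model)
        with pytest.raises(ValueError):
            region_mean_temperature(tmap, np.zeros((3, 5), dtype=bool))


class TestTemperatureResolution:
    def test_iqr_definition_on_separated_levels(self, rng):
        # narrow spread: adjacent 0.9-degree levels are resolved
        samples = {t: t + rng.normal(0, 0.05, 500) for t in (31.7, 32.6, 33.5)}
        step, rms = temperature_resolution(samples)
        assert step == pytest.approx(0.9)
        assert rms == pytest.approx(0.05, rel=0.2)

    def test_unresolvable_when_spread_dominates(self, rng):
        samples = {t: t + rng.normal(0, 5.0, 500) for t in (31.7, 32.6)}
        step, _ = temperature_resolution(samples)
        assert step == float("inf")

    def test_constant_forward_model_consistency(self):
        # Stefan-Boltzmann constant wired into the model
        model = CalibrationModel.uniform((2, 2), C=2.0, Delta=1.0)
        x = model.radiance(300.0)
        assert np.allclose(x, 2.0 * 0.98 * STEFAN_BOLTZMANN * 300.0**4 + 1.0)
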