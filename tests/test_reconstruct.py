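"""Laplace interpolation of unmeasured signals and closed-form recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermopix import (
    CodingScheme,
    ScanRecord,
    ThermalScene,
    laplace_interpolate,
    reassemble_fov,
    reconstruct,
    simulate_full_scan,
    simulate_scan,
)
from thermopix.reconstruct import gauss_seidel_interpolate


@pytest.fixture
def scheme15():
    return CodingScheme(p=3, q=5, m=5)


def _record_from_rows(S, rows, x):
    rows = np.asarray(rows, dtype=np.int64)
    return ScanRecord(measured_rows=rows, bucket=S.matrix[rows] @ np.asarray(x).ravel())


class TestLaplaceInterpolate:
    def test_fully_sampled_is_identity(self, S143, scheme_full, rng):
        scene = ThermalScene(rng.uniform(0, 1, (11, 13)))
        rec = simulate_full_scan(scene, S143)
        interp = laplace_interpolate(rec, scheme_full)
        full = np.zeros(143)
        full[rec.measured_rows] = rec.bucket
        assert np.array_equal(interp.values, full)
        assert interp.measured_mask.all()

    def test_single_hole_is_four_neighbor_average(self, scheme15):
        # one unmeasured index whose four modular neighbors are measured:
        # the interpolant is exactly their mean
        n, q, hole = 15, 5, 7
        vals = np.arange(1.0, 16.0)
        rows = np.array([u for u in range(n) if u != hole])
        rec = ScanRecord(measured_rows=rows, bucket=vals[rows])
        out = laplace_interpolate(rec, scheme15)
        expected = (vals[8] + vals[6] + vals[12] + vals[2]) / 4  # u+-1, u+-q
        assert out.values[hole] == pytest.approx(expected, abs=1e-12)
        assert np.array_equal(out.values[rows], vals[rows])

    def test_constant_data_interpolates_to_constant(self, scheme15):
        rows = np.array([0, 3, 8, 11])
        rec = ScanRecord(measured_rows=rows, bucket=np.full(4, 5.5))
        out = laplace_interpolate(rec, scheme15)
        assert np.allclose(out.values, 5.5)

    def test_harmonic_equation_at_every_unmeasured_index(self, S143, scheme91, rng):
        scene = ThermalScene(rng.uniform(0, 1, (11, 13)))
        rec = simulate_scan(scene, S143, scheme91)
        y = laplace_interpolate(rec, scheme91).values
        n, q = 143, 13
        measured = set(rec.measured_rows.tolist())
        for u in range(n):
            if u in measured:
                continue
            avg = (y[(u + 1) % n] + y[(u - 1) % n] + y[(u + q) % n] + y[(u - q) % n]) / 4
            assert abs(y[u] - avg) < 1e-10

    @pytest.mark.parametrize("n_measured", [1, 4, 9, 14])
    def test_matches_gauss_seidel_oracle_order_15(self, S15, scheme15, rng, n_measured):
        x = rng.uniform(0, 1, 15)
        rows = np.sort(rng.choice(15, n_measured, replace=False))
        rec = _record_from_rows(S15, rows, x)
        a = laplace_interpolate(rec, scheme15).values
        b = gauss_seidel_interpolate(rec, scheme15, tol=1e-13).values
        assert np.abs(a - b).max() < 1e-9

    def test_maximum_principle(self, S143, scheme91, rng):
        # interpolated values stay within [min, max] of measured data
        scene = ThermalScene(rng.uniform(0, 1, (11, 13)))
        rec = simulate_scan(scene, S143, scheme91)
        out = laplace_interpolate(rec, scheme91)
        lo, hi = rec.bucket.min(), rec.bucket.max()
        assert out.values.min() >= lo - 1e-9
        assert out.values.max() <= hi + 1e-9

    def test_empty_and_duplicate_records_rejected(self, scheme15):
        with pytest.raises(ValueError):
            laplace_interpolate(ScanRecord(np.array([], dtype=int), np.array([])), scheme15)
        with pytest.raises(ValueError):
            laplace_interpolate(ScanRecord(np.array([1, 1]), np.array([0.0, 0.0])), scheme15)


class TestReconstruct:
    def test_full_noiseless_scan_recovers_scene(self, S143, scheme_full, rng):
        for _ in range(10):
            scene = ThermalScene(rng.uniform(0, 1, (11, 13)))
            rec = simulate_full_scan(scene, S143)
            img = reconstruct(laplace_interpolate(rec, scheme_full), S143)
            assert np.abs(img.grid - scene.radiance).max() < 1e-9

    def test_zero_signal_gives_zero_image(self, S143):
        img = reconstruct(np.zeros(143), S143)
        assert np.all(img.grid == 0)

    def test_compressed_smooth_scene_error_locked(self, S143, scheme91):
        # regression lock: m=91 noiseless reconstruction of a smooth scene
        ii, jj = np.mgrid[0:11, 0:13]
        scene = ThermalScene(1 + 0.3 * np.sin(ii / 3) + 0.3 * np.cos(jj / 4))
        rec = simulate_scan(scene, S143, scheme91)
        img = reconstruct(laplace_interpolate(rec, scheme91), S143)
        rel_rmse = np.sqrt(((img.grid - scene.radiance) ** 2).mean()) / scene.radiance.mean()
        assert rel_rmse < 0.05

    def test_length_mismatch(self, S143):
        with pytest.raises(ValueError):
            reconstruct(np.zeros(100), S143)

    def test_error_nonincreasing_in_scan_length(self, S143, rng):
        # averaged over random smooth scenes, more measurements never hurt
        ms = [40, 70, 100, 143]
        mean_err = []
        for m in ms:
            scheme = CodingScheme(p=11, q=13, m=m)
            errs = []
            for _ in range(20):
                base = rng.uniform(0.5, 1.5, (4, 5))
                # smooth random scene: bilinear upsample of a coarse field
                from scipy.ndimage import zoom

                smooth = zoom(base, (11 / 4, 13 / 5), order=1)
                scene = ThermalScene(np.clip(smooth, 0, None))
                rec = simulate_scan(scene, S143, scheme)
                img = reconstruct(laplace_interpolate(rec, scheme), S143)
                errs.append(np.sqrt(((img.grid - scene.radiance) ** 2).mean()))
            mean_err.append(np.mean(errs))
        assert all(a >= b - 1e-12 for a, b in zip(mean_err, mean_err[1:]))


class TestReassembleFov:
    def test_region_shapes(self, S143, scheme91, rng):
        img = reconstruct(rng.uniform(0, 1, 143), S143)
        left, right = reassemble_fov(img, scheme91)
        assert left.shape == (11, 7)
        assert right.shape == (11, 6)

    def test_regions_restore_full_grid(self, S143, scheme91, rng):
        from thermopix import reassemble_pattern

        img = reconstruct(rng.uniform(0, 1, 143), S143)
        left, right = reassemble_fov(img, scheme91)
        assert np.allclose(reassemble_pattern(left, right, scheme91), img.grid)

    @given(fliplr=st.booleans(), flipud=st.booleans())
    @settings(max_examples=8, deadline=None)
    def test_flips_honored_and_invertible(self, S143, fliplr, flipud):
        from thermopix import FlipConfig, reassemble_pattern

        scheme = CodingScheme(
            p=11, q=13, m=91,
            flip_config=FlipConfig(part_a_fliplr=fliplr, part_b_flipud=flipud),
        )
        rng = np.random.default_rng(5)
        img = reconstruct(rng.uniform(0, 1, 143), S143)
        left, right = reassemble_fov(img, scheme)
        assert np.allclose(reassemble_pattern(left, right, scheme), img.grid)
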