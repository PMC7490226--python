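"""Thickness-map construction, fovea detection, magnification correction,
thickness-to-density conversion and the GCL-peak scaling analysis."""

import numpy as np
import pytest

from drasdo import AL0, build_eye
from drasdo.density_maps import synthetic_density
from drasdo.fixtures import FixtureSpec, make_thickness_cohort
from drasdo.oct import (MmRaster, ThicknessMap, build_thickness_map,
                        find_fovea, gcl_peak_ellipse, magnification_correct,
                        raza_hood_volumetric, scaling_analysis,
                        subject_density, _density_map_to_raster)


def _bscan_samples(fn, n_scans=25, n_ax=60, half=12.0):
    ys = np.linspace(-half, half, n_scans)
    xs = np.linspace(-14.0, 14.0, n_ax)
    xx, yy = np.meshgrid(xs, ys)
    return xx.ravel(), yy.ravel(), fn(xx, yy).ravel()


class TestBuildThicknessMap:
    def test_constant_surface_recovered(self):
        x, y, t = _bscan_samples(lambda x, y: np.full_like(x, 30.0))
        tm = build_thickness_map(x, y, t, al_mm=24.0, shape=(96, 96))
        assert np.max(np.abs(tm.data_um[tm.valid] - 30.0)) < 0.1

    def test_ridge_profile_rmse_below_one_micron(self):
        def ridge(x, y):
            return 30.0 + 20.0 * np.exp(-(np.hypot(x, y) - 4.0) ** 2 / 8.0)

        x, y, t = _bscan_samples(ridge)
        tm = build_thickness_map(x, y, t, al_mm=24.0, shape=(128, 128))
        pitch = tm.pitch_deg
        xs = (np.arange(128) - 64) * pitch
        ys = (64 - np.arange(128)) * pitch
        gx, gy = np.meshgrid(xs, ys)
        want = ridge(gx, gy)
        interior = tm.valid & (np.abs(gx) < 13.0) & (np.abs(gy) < 11.0)
        rmse = float(np.sqrt(np.mean((tm.data_um[interior] - want[interior]) ** 2)))
        assert rmse < 1.0

    def test_outside_coverage_zero_and_invalid(self):
        x, y, t = _bscan_samples(lambda x, y: np.full_like(x, 25.0), half=8.0)
        tm = build_thickness_map(x, y, t, al_mm=24.0, shape=(96, 96))
        top_rows = tm.data_um[:5]       # beyond the 8-degree scan coverage
        assert np.all(top_rows == 0.0)
        assert not tm.valid[:5].any()

    def test_too_few_bscans_rejected(self):
        x = np.linspace(-5, 5, 50)
        y = np.zeros_like(x)
        with pytest.raises(ValueError, match="B-scan"):
            build_thickness_map(x, y, np.full_like(x, 30.0), al_mm=24.0)

    def test_missing_foveal_coverage_rejected(self):
        x, y, t = _bscan_samples(lambda x, y: np.full_like(x, 30.0))
        far = np.hypot(x, y) > 5.0
        with pytest.raises(ValueError, match="fovea"):
            build_thickness_map(x[far], y[far], t[far], al_mm=24.0)


class TestFindFovea:
    def _pit_map(self, center_px, shape=(160, 160), fov=30.0):
        pitch = fov / shape[1]
        rows, cols = np.indices(shape)
        d2 = ((rows - center_px[0]) ** 2 + (cols - center_px[1]) ** 2) * pitch ** 2
        data = 250.0 - 80.0 * np.exp(-d2 / (2.0 * 1.0 ** 2))
        return ThicknessMap(data, (fov, fov), 24.0)

    def test_detects_injected_pit_within_three_pixels(self):
        tm = self._pit_map((100, 90))
        res = find_fovea(tm)
        assert abs(res.px[0] - 100) <= 3 and abs(res.px[1] - 90) <= 3
        assert res.confident

    def test_flat_map_flags_low_confidence(self):
        tm = ThicknessMap(np.full((120, 120), 50.0), (30.0, 30.0), 24.0)
        with pytest.warns(UserWarning, match="low-confidence"):
            res = find_fovea(tm)
        assert not res.confident

    def test_invariant_to_constant_offset(self):
        tm = self._pit_map((70, 85))
        shifted = ThicknessMap(tm.data_um + 100.0, tm.fov_deg, 24.0)
        assert find_fovea(tm).px == find_fovea(shifted).px


class TestMagnificationCorrect:
    def test_extent_matches_eye_conversion(self):
        tm = ThicknessMap(np.full((96, 96), 40.0), (30.0, 30.0), AL0,
                          fovea_px=(48, 48))
        mm = magnification_correct(tm)
        eye = build_eye(AL0)
        assert mm.half_extent_mm == pytest.approx(float(eye.deg_to_mm(15.0)), abs=1e-9)

    def test_two_eyes_scale_by_conversion_ratio(self):
        spec = FixtureSpec(seed=3, n_eyes=1, noise_um=0.0, shape=(128, 128))
        tm = make_thickness_cohort(spec)[0]
        mm1 = magnification_correct(tm)
        # the mm extent ratio equals the eyes' own deg->mm ratio (within 2%
        # of the axial-length ratio; the residual is ocular magnification)
        tm2 = ThicknessMap(tm.data_um, tm.fov_deg, tm.al_mm * 1.05,
                           fovea_px=tm.fovea_px)
        mm2 = magnification_correct(tm2)
        ratio = mm2.half_extent_mm / mm1.half_extent_mm
        assert ratio == pytest.approx(1.05, rel=0.02)

    def test_fixture_surface_recovered_in_mm_frame(self):
        from drasdo.fixtures import _thickness_surface
        spec = FixtureSpec(seed=5, n_eyes=1, noise_um=0.0, shape=(160, 160))
        tm = make_thickness_cohort(spec)[0]
        mm = magnification_correct(tm)
        xs, ys = mm.coords()
        gx, gy = np.meshgrid(xs, ys)
        a = spec.axes0_mm[0] * tm.al_mm / AL0
        b = spec.axes0_mm[1] * tm.al_mm / AL0
        want = _thickness_surface(gx, gy, a, b, spec)
        inner = np.hypot(gx, gy) < 3.0
        rmse = float(np.sqrt(np.mean((mm.data[inner] - want[inner]) ** 2)))
        assert rmse < 0.5

    def test_requires_fovea(self):
        tm = ThicknessMap(np.full((64, 64), 40.0), (30.0, 30.0), 24.0)
        with pytest.raises(ValueError, match="fovea"):
            magnification_correct(tm)


class TestRazaHood:
    def test_uniform_division(self):
        dens = np.full((64, 64), 10000.0)
        mean_t = MmRaster(np.full((64, 64), 50.0), 3.5, AL0)
        vol = raza_hood_volumetric(dens, mean_t)
        assert np.allclose(vol.data[vol.valid], 200000.0)

    def test_thin_regions_masked(self):
        dens = np.full((64, 64), 10000.0)
        t = np.full((64, 64), 50.0)
        t[30:34, 30:34] = 1.0       # foveal pit / padded zeros
        vol = raza_hood_volumetric(dens, MmRaster(t, 3.5, AL0))
        assert not vol.valid[31, 31]
        assert np.isnan(vol.data[31, 31])

    def test_linear_in_mean_thickness(self):
        dens = np.full((32, 32), 8000.0)
        v1 = raza_hood_volumetric(dens, MmRaster(np.full((32, 32), 40.0), 3.0, AL0))
        v2 = raza_hood_volumetric(dens, MmRaster(np.full((32, 32), 80.0), 3.0, AL0))
        assert np.allclose(v2.data[v2.valid], v1.data[v1.valid] / 2.0)

    def test_misaligned_frames_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            raza_hood_volumetric(np.ones((32, 32)),
                                 MmRaster(np.full((64, 64), 50.0), 3.0, AL0))


class TestSubjectDensity:
    def test_identity_round_trip(self, synth_map):
        mean_t = MmRaster(np.full((96, 96), 50.0), 3.5, AL0)
        vol = raza_hood_volumetric(synth_map, mean_t)
        subj = subject_density(vol, MmRaster(np.full((96, 96), 50.0), 3.5, AL0))
        direct = _density_map_to_raster(synth_map, 3.5, 96)
        ok = vol.valid & subj.valid
        assert np.nanmax(np.abs(subj.data[ok] - direct[ok])) < 1e-9

    def test_linear_in_subject_thickness(self, synth_map):
        mean_t = MmRaster(np.full((64, 64), 50.0), 3.5, AL0)
        vol = raza_hood_volumetric(synth_map, mean_t)
        d1 = subject_density(vol, MmRaster(np.full((64, 64), 50.0), 3.5, AL0))
        d2 = subject_density(vol, MmRaster(np.full((64, 64), 40.0), 3.5, AL0))
        ok = d1.valid
        assert np.allclose(d2.data[ok], 0.8 * d1.data[ok])

    def test_global_expansion_scaling_applied(self, synth_map):
        mean_t = MmRaster(np.full((96, 96), 50.0), 3.5, AL0)
        vol = raza_hood_volumetric(synth_map, mean_t)
        al = AL0 * 1.1
        subj = subject_density(vol, MmRaster(np.full((96, 96), 50.0),
                                             3.5 * 1.1, al), al_mm=al)
        # at the scaled position of the ridge the density is peak/(s^2)
        s = 1.1
        xs, ys = subj.coords()
        j = np.argmin(np.abs(xs - 1.0 * s))
        i = np.argmin(np.abs(ys))
        direct = _density_map_to_raster(synth_map, 3.5, 96)
        j0 = np.argmin(np.abs(np.linspace(-3.5, 3.5, 96) - 1.0))
        assert subj.data[i, j] == pytest.approx(
            float(synth_map.density_at(0.0, xs[j] / s)) / s ** 2, rel=0.02)


class TestEllipseAndScaling:
    def _ellipse_map(self, a, b, noise=0.0, seed=0, n=192, half=3.5):
        spec = FixtureSpec(axes0_mm=(a, b), noise_um=noise, seed=seed)
        from drasdo.fixtures import _thickness_surface
        xs = (np.arange(n) - n // 2) * (2 * half / n)
        ys = ((n // 2) - np.arange(n)) * (2 * half / n)
        gx, gy = np.meshgrid(xs, ys)
        data = _thickness_surface(gx, gy, a, b, spec)
        if noise:
            data = data + np.random.default_rng(seed).normal(0, noise, data.shape)
        return MmRaster(np.clip(data, 0, None), half, AL0)

    def test_known_ellipse_recovered(self):
        fit = gcl_peak_ellipse(self._ellipse_map(2.0, 1.6))
        assert fit.major_mm == pytest.approx(2.0, abs=0.01)
        assert fit.minor_mm == pytest.approx(1.6, abs=0.01)

    def test_circular_map_has_equal_axes(self):
        fit = gcl_peak_ellipse(self._ellipse_map(1.8, 1.8))
        assert fit.major_mm == pytest.approx(fit.minor_mm, abs=0.01)

    def test_constant_offset_leaves_peaks_unchanged(self):
        m = self._ellipse_map(2.0, 1.6)
        m2 = MmRaster(m.data + 10.0, m.half_extent_mm, m.al_mm)
        f1, f2 = gcl_peak_ellipse(m), gcl_peak_ellipse(m2)
        assert f1.major_mm == pytest.approx(f2.major_mm, abs=1e-6)
        assert f1.minor_mm == pytest.approx(f2.minor_mm, abs=1e-6)

    def test_flat_map_fails_with_few_peaks(self):
        flat = MmRaster(np.full((96, 96), 30.0), 3.5, AL0)
        with pytest.raises(ValueError):
            gcl_peak_ellipse(flat)

    def test_noiseless_geometric_cohort_mae_below_tolerance(self):
        spec = FixtureSpec(seed=11, n_eyes=10, noise_um=0.0, shape=(160, 160))
        cohort = make_thickness_cohort(spec)
        fits = [gcl_peak_ellipse(magnification_correct(t)) for t in cohort]
        res = scaling_analysis(fits, [t.al_mm for t in cohort])
        assert max(res.mae_geometric) < 1e-3
        assert res.slope[0] > 0 and res.slope[1] > 0

    def test_noisy_cohort_linear_and_geometric_equivalent(self):
        spec = FixtureSpec(seed=12, n_eyes=24, noise_um=0.0,
                           axis_jitter_mm=0.05, shape=(128, 128))
        cohort = make_thickness_cohort(spec)
        fits = [gcl_peak_ellipse(magnification_correct(t)) for t in cohort]
        res = scaling_analysis(fits, [t.al_mm for t in cohort])
        for ml, mg in zip(res.mae_linear, res.mae_geometric):
            assert mg == pytest.approx(ml, rel=0.35, abs=0.01)

    def test_al_independent_axes_favor_linear_model(self):
        rng = np.random.default_rng(4)
        als = np.linspace(21.0, 27.0, 16)
        from drasdo.oct import EllipseFit
        fits = [EllipseFit((0.0, 0.0), 2.0 + 1e-4 * rng.standard_normal(),
                           1.6 + 1e-4 * rng.standard_normal(), 0.0)
                for _ in als]
        res = scaling_analysis(fits, als)
        assert res.mae_geometric[0] > res.mae_linear[0]
        assert res.mae_geometric[1] > res.mae_linear[1]
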