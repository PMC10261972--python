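import numpy as np
import pytest

from sphagspec import ratio_index
from sphagspec.moisture import masses_from_frame, moisture_content
from sphagspec.preprocess import smooth_library
from sphagspec.ratio_index import (
    RatioIndexScan,
    fit_ri_on_moisture,
    scan_all_pairs,
    surface_summary,
)
from sphagspec.spectral_io import WavelengthGrid
from sphagspec.synthetic import SimulationConfig, generate_library, single_well_models
from tests.conftest import make_library

GRID = WavelengthGrid(1000, 1090, 10)  # 10 bands


def ols_oracle(y, x):
    """Normal-equations oracle for simple OLS with n-denominator RMSE."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - slope * x - intercept
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1 - (resid**2).sum() / sst if sst > 0 else 0.0
    return slope, intercept, r2, np.sqrt((resid**2).sum() / n)


class TestRatioIndex:
    def test_same_band_is_unity(self):
        spec = np.linspace(0.1, 0.9, len(GRID))
        assert ratio_index.ratio_index(spec, GRID, 1040, 1040) == 1.0

    def test_forced_arithmetic(self):
        spec = np.full(len(GRID), 0.8)
        spec[GRID.index_of(1020)] = 0.4
        assert ratio_index.ratio_index(spec, GRID, 1020, 1050) == pytest.approx(0.5)

    def test_flat_spectrum_unity_for_all_pairs(self):
        spec = np.full(len(GRID), 0.37)
        for l1 in GRID.wavelengths[:3]:
            for l2 in GRID.wavelengths[-3:]:
                assert ratio_index.ratio_index(spec, GRID, l1, l2) == 1.0

    def test_zero_denominator_raises(self):
        spec = np.full(len(GRID), 0.5)
        spec[GRID.index_of(1080)] = 0.0
        with pytest.raises(ZeroDivisionError):
            ratio_index.ratio_index(spec, GRID, 1000, 1080)


class TestFit:
    def test_exact_line_recovered(self):
        m = np.array([20.0, 40.0, 60.0, 80.0])
        ri = -0.02 * m + 2.5
        fit = fit_ri_on_moisture(ri, m)
        assert fit.slope == pytest.approx(-0.02, abs=1e-12)
        assert fit.intercept == pytest.approx(2.5, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_zero_slope_and_r2(self):
        fit = fit_ri_on_moisture(np.full(5, 1.3), np.arange(5.0))
        assert fit.slope == 0.0 and fit.r2 == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(3, 40)
            m = rng.uniform(0, 100, n)
            ri = rng.normal(size=n)
            fit = fit_ri_on_moisture(ri, m)
            slope, intercept, r2, rmse = ols_oracle(ri, m)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.r2 == pytest.approx(r2, abs=1e-10)
            assert fit.rmse == pytest.approx(rmse, abs=1e-10)

    def test_zero_moisture_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_ri_on_moisture(np.arange(4.0), np.full(4, 50.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_ri_on_moisture(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def _planted_pair_library(seed=0, n=8):
    """Spectra where RI(1020, 1050) is an exact linear function of moisture
    and every other band is random."""
    rng = np.random.default_rng(seed)
    m = np.linspace(20, 90, n)
    spectra = rng.uniform(0.2, 0.8, size=(n, len(GRID)))
    j_den = GRID.index_of(1050)
    j_num = GRID.index_of(1020)
    spectra[:, j_den] = 0.5
    spectra[:, j_num] = 0.5 * (2.0 - 0.015 * m)
    lib = make_library(
        GRID,
        spectra,
        ["fuscum"] * n,
        ["0h"] * n,
        [f"s{i:02d}" for i in range(n)],
    )
    return lib, {f"s{i:02d}": m[i] for i in range(n)}


class TestScan:
    def test_planted_perfect_pair_found(self):
        lib, moist = _planted_pair_library()
        scan = scan_all_pairs(lib, moist, time="0h")
        l1, l2, slope, intercept, r2, rmse = scan.best
        assert (l1, l2) == (1020.0, 1050.0)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        # RI = 0.5*(2.0 - 0.015 m) / 0.5 = 2.0 - 0.015 m
        assert slope == pytest.approx(-0.015, abs=1e-12)
        assert intercept == pytest.approx(2.0, abs=1e-12)

    def test_diagonal_has_zero_r2(self):
        lib, moist = _planted_pair_library()
        scan = scan_all_pairs(lib, moist, time="0h")
        np.testing.assert_array_equal(np.diag(scan.r2_surface), 0.0)
        np.testing.assert_array_equal(np.diag(scan.rmse_surface), 0.0)

    def test_surface_matches_per_pair_ols(self):
        lib, moist = _planted_pair_library(seed=3)
        scan = scan_all_pairs(lib, moist, time="0h")
        m = np.array([moist[f"s{i:02d}"] for i in range(8)])
        rng = np.random.default_rng(1)
        w = scan.wavelengths
        for _ in range(100):
            i, j = rng.integers(0, len(w), 2)
            ri = lib.reflectance[:, i] / lib.reflectance[:, j]
            if i == j:
                continue
            slope, intercept, r2, rmse = ols_oracle(ri, m)
            assert scan.r2_surface[i, j] == pytest.approx(r2, abs=1e-9)
            assert scan.slope_surface[i, j] == pytest.approx(slope, abs=1e-9)
            assert scan.intercept_surface[i, j] == pytest.approx(intercept, abs=1e-9)
            assert scan.rmse_surface[i, j] == pytest.approx(rmse, abs=1e-9)

    def test_swapping_bands_changes_r2(self):
        # RI -> 1/RI is nonlinear, so the surface is not symmetric; find a
        # witness pair on synthetic spectra
        lib, moist = _planted_pair_library(seed=5)
        scan = scan_all_pairs(lib, moist, time="0h")
        r2 = scan.r2_surface
        asym = np.abs(r2 - r2.T)
        assert np.nanmax(asym) > 1e-4

    def test_stride_subset_never_beats_full_scan(self):
        lib, moist = _planted_pair_library(seed=7)
        full = scan_all_pairs(lib, moist, time="0h", stride_nm=1)
        coarse = scan_all_pairs(lib, moist, time="0h", stride_nm=3)
        assert np.nanmax(coarse.r2_surface) <= np.nanmax(full.r2_surface) + 1e-15

    def test_near_zero_denominator_masked(self):
        lib, moist = _planted_pair_library(seed=9)
        lib.reflectance[2, GRID.index_of(1080)] = 1e-6
        scan = scan_all_pairs(lib, moist, time="0h")
        j = GRID.index_of(1080)
        assert np.isnan(scan.r2_surface[:, j]).all()
        # the band is still usable as a numerator against other denominators
        assert not np.isnan(np.delete(scan.r2_surface[j, :], j)).any()

    def test_missing_moisture_named(self):
        lib, moist = _planted_pair_library()
        moist.pop("s03")
        with pytest.raises(KeyError, match="s03"):
            scan_all_pairs(lib, moist, time="0h")

    def test_wavelength_range_restricts_axes(self):
        lib, moist = _planted_pair_library()
        scan = scan_all_pairs(lib, moist, time="0h", wavelength_range=(1020, 1060))
        assert scan.wavelengths.min() == 1020 and scan.wavelengths.max() == 1060


class TestRecovery:
    def test_planted_well_drives_best_pair(self):
        """A single moisture-scaled absorption well must pull the best
        band pair onto itself (fresh samples, one seed; the multi-seed
        version is an acceptance check)."""
        cfg = SimulationConfig(seed=0)
        lib, masses = generate_library(cfg, models=single_well_models(1450.0))
        lib = smooth_library(lib)
        moist = {
            m.sample_id: 100 * moisture_content(m).moist_fraction
            for m in masses_from_frame(masses)
            if m.measurement_time == "0h"
        }
        scan = scan_all_pairs(lib, moist, time="0h", stride_nm=5)
        l1, _, _, _, r2, _ = scan.best
        assert abs(l1 - 1450.0) <= 60.0
        assert r2 >= 0.7


def _toy_scan(r2):
    r2 = np.asarray(r2, dtype=float)
    z = np.zeros_like(r2)
    return RatioIndexScan(
        wavelengths=1000 + 10.0 * np.arange(r2.shape[0]),
        time="0h",
        r2_surface=r2,
        slope_surface=z,
        intercept_surface=z,
        rmse_surface=z,
        n_samples=9,
    )


class TestSurfaceSummary:
    def test_subthreshold_surface_gives_empty_list(self):
        assert surface_summary(_toy_scan(np.full((5, 5), 0.2)), 0.7) == []

    def test_single_block_bounding_box(self):
        r2 = np.zeros((6, 6))
        r2[1:4, 2:5] = 0.9
        (reg,) = surface_summary(_toy_scan(r2), 0.7)
        assert (reg.l1_start_nm, reg.l1_end_nm) == (1010.0, 1030.0)
        assert (reg.l2_start_nm, reg.l2_end_nm) == (1020.0, 1040.0)
        assert reg.n_pairs == 9 and reg.max_r2 == pytest.approx(0.9)

    def test_two_disjoint_blocks_found(self):
        # flood-fill oracle: two planted blocks -> exactly two components
        r2 = np.zeros((8, 8))
        r2[0:2, 0:2] = 0.8
        r2[5:8, 5:7] = 0.95
        regions = surface_summary(_toy_scan(r2), 0.7)
        assert len(regions) == 2
        assert sorted(r.n_pairs for r in regions) == [4, 6]

    def test_nan_pairs_never_in_regions(self):
        r2 = np.full((4, 4), np.nan)
        r2[0, 1] = 0.9
        (reg,) = surface_summary(_toy_scan(r2), 0.7)
        assert reg.n_pairs == 1
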