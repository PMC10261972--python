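import itertools

import numpy as np
import pytest
from scipy.special import expit

from sphagspec import band_stats
from sphagspec.spectral_io import WavelengthGrid
from tests.conftest import make_library


def enumerated_rank_sum_p(x, y):
    """Independent oracle: exact two-sided p by enumerating all group
    assignments of the pooled sample (2*min-tail definition, clipped at 1)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = sum(xi > yj for xi in x for yj in y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        us.append(sum(a > b for a in xs for b in ys))
    us = np.array(us)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestRankSum:
    def test_disjoint_small_groups_exact_tenth(self):
        # all 20 assignments enumerable; the observed split is one of the
        # two most extreme -> p = 2/20
        assert band_stats.rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert band_stats.rank_sum_test([0.5] * 4, [0.5] * 4) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for n, m in [(3, 3), (4, 5), (6, 2)]:
            x = rng.normal(size=n)
            y = rng.normal(size=m) + 0.5
            assert band_stats.rank_sum_test(x, y) == pytest.approx(
                enumerated_rank_sum_p(x, y), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.1, 0.5, 8)
        y = rng.uniform(0.2, 0.6, 8)
        assert band_stats.rank_sum_test(x, y) == pytest.approx(
            band_stats.rank_sum_test(np.exp(x), np.exp(y)), abs=1e-12
        )


class TestWilcoxonBands:
    GRID = WavelengthGrid(1000, 1400, 10)

    def _library(self, shift_band=None, seed=0):
        rng = np.random.default_rng(seed)
        nb = len(self.GRID)
        spectra, species, times, ids = [], [], [], []
        for i in range(10):
            base = 0.3 + 0.02 * rng.normal(size=nb)
            time = "0h" if i < 5 else "1week"
            if time == "1week" and shift_band is not None:
                lo, hi = shift_band
                w = self.GRID.wavelengths
                base = base + 0.3 * ((w >= lo) & (w <= hi))
            spectra.append(base)
            species.append("fuscum")
            times.append(time)
            ids.append(f"fus_{i:02d}")
        return make_library(self.GRID, spectra, species, times, ids)

    def test_identical_groups_nowhere_significant(self):
        rng = np.random.default_rng(5)
        nb = len(self.GRID)
        spectra = [0.3 + 0.05 * rng.normal(size=nb) for _ in range(3)]
        lib = make_library(
            self.GRID,
            spectra * 2,
            ["fuscum"] * 6,
            ["0h"] * 3 + ["1week"] * 3,
            [f"fus_{i}" for i in range(6)],
        )
        mask = band_stats.wilcoxon_bands(lib, "fuscum")
        assert not mask.significant.any()
        assert mask.regions == []

    def test_planted_shift_recovered_as_region(self):
        mask = band_stats.wilcoxon_bands(
            self._library(shift_band=(1190, 1300)), "fuscum"
        )
        covered = [r for r in mask.regions if r[0] <= 1190 and r[1] >= 1300]
        assert covered, f"regions {mask.regions} do not cover the shifted band"

    def test_regions_partition_significant_indices(self):
        mask = band_stats.wilcoxon_bands(
            self._library(shift_band=(1000, 1050)), "fuscum"
        )
        w = mask.grid.wavelengths
        in_regions = np.zeros(len(w), dtype=bool)
        for lo, hi in mask.regions:
            in_regions |= (w >= lo) & (w <= hi)
        np.testing.assert_array_equal(in_regions, mask.significant)

    def test_too_few_samples_rejected(self):
        lib = self._library().subset(species="fuscum")
        small = make_library(
            lib.grid,
            lib.reflectance[:3],
            ["fuscum"] * 3,
            ["0h", "0h", "1week"],
            ["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="≥2 samples"):
            band_stats.wilcoxon_bands(small, "fuscum")


class TestREP:
    GRID = WavelengthGrid(600, 900, 1)

    def test_logistic_inflection_recovered(self):
        w = self.GRID.wavelengths
        spec = 0.05 + 0.4 * expit((w - 715.0) / 10.0)
        rep = band_stats.compute_rep(spec, self.GRID)
        assert rep.rep_nm == 715.0

    def test_linear_ramp_tie_breaks_to_window_start(self):
        spec = 0.001 * self.GRID.wavelengths
        rep = band_stats.compute_rep(spec, self.GRID)
        assert rep.rep_nm == 680.0

    def test_flat_window_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            band_stats.compute_rep(np.full(len(self.GRID), 0.3), self.GRID)

    def test_four_point_method_on_straight_edge(self):
        # reflectance linear between 670 and 780 -> midpoint interpolation
        # lands mid-edge
        w = self.GRID.wavelengths
        spec = np.interp(w, [600, 670, 780, 900], [0.05, 0.05, 0.45, 0.45])
        rep = band_stats.compute_rep(spec, self.GRID, method="linear_four_point")
        assert rep.rep_nm == pytest.approx(725.0, abs=1.0)

    def test_synthetic_species_reps_inside_window(self, default_library):
        lib, _ = default_library
        reps = band_stats.rep_library(lib.subset(time="0h"))
        assert reps.rep_nm.between(680, 750).all()
        # mesotrophic species have higher red edges than bog species
        means = reps.groupby("species").rep_nm.mean()
        assert means["riparium"] > means["cuspidatum"]


class TestREPGroupTest:
    def test_identical_groups_p_one(self):
        reps = [band_stats.REPResult(700.0)] * 3
        assert band_stats.rep_group_test(reps, reps) == 1.0

    def test_disjoint_triplets_exact_tenth(self):
        a = [band_stats.REPResult(x) for x in (700, 701, 702)]
        b = [band_stats.REPResult(x) for x in (710, 711, 712)]
        assert band_stats.rep_group_test(a, b) == pytest.approx(0.1)

    def test_planted_habitat_shift_detected_at_n10(self):
        rng = np.random.default_rng(2)
        meso = 715 + 3 * rng.normal(size=10)
        ombro = 705 + 3 * rng.normal(size=10)
        assert band_stats.rep_group_test(meso, ombro) < 0.05


class TestVarianceExplained:
    GRID = WavelengthGrid(600, 650, 10)

    def _lib(self, values_by_record, species, times=None):
        n = len(species)
        spectra = [np.full(len(self.GRID), v) for v in values_by_record]
        return make_library(
            self.GRID,
            spectra,
            species,
            times or ["0h"] * n,
            [f"s{i}" for i in range(n)],
        )

    def test_forced_sums_of_squares(self):
        # A = {0.2, 0.4}, B = {0.6, 0.8}: SSB = 0.16, SST = 0.2 -> 0.8
        lib = self._lib([0.2, 0.4, 0.6, 0.8], ["fuscum"] * 2 + ["fallax"] * 2)
        curve = band_stats.variance_explained(lib, "species")
        np.testing.assert_allclose(curve.r2, 0.8, rtol=1e-12)

    def test_within_group_constants_give_unity(self):
        lib = self._lib([0.2, 0.2, 0.7, 0.7], ["fuscum"] * 2 + ["fallax"] * 2)
        np.testing.assert_allclose(
            band_stats.variance_explained(lib, "species").r2, 1.0
        )

    def test_zero_total_variance_gives_zero(self):
        lib = self._lib([0.5, 0.5, 0.5, 0.5], ["fuscum"] * 2 + ["fallax"] * 2)
        np.testing.assert_array_equal(
            band_stats.variance_explained(lib, "species").r2, 0.0
        )

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        species = ["fuscum"] * 3 + ["fallax"] * 4 + ["centrale"] * 3
        vals = rng.uniform(0, 1, size=len(species))
        lib = self._lib(vals, species)
        r2 = band_stats.variance_explained(lib, "species").r2[0]
        # brute-force OLS on indicator design
        x = np.zeros((len(species), 3))
        for i, sp in enumerate(species):
            x[i, ["fuscum", "fallax", "centrale"].index(sp)] = 1.0
        beta, *_ = np.linalg.lstsq(x, vals, rcond=None)
        sse = np.sum((vals - x @ beta) ** 2)
        sst = np.sum((vals - vals.mean()) ** 2)
        assert r2 == pytest.approx(1 - sse / sst, abs=1e-10)

    def test_permuted_labels_lose_explanatory_power(self, default_library):
        lib, _ = default_library
        sub = lib.subset(time="0h")
        planted = band_stats.variance_explained(sub, "species").r2
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(sub))
        shuffled = make_library(
            sub.grid,
            sub.reflectance,
            [sub.meta[i].species for i in perm],
            [m.measurement_time for m in sub.meta],
            [f"p{i}" for i in range(len(sub))],
        )
        permuted = band_stats.variance_explained(shuffled, "species").r2
        # under the null E[R2] = (k-1)/(n-1) ~ 0.09; allow sampling slack
        assert permuted.mean() < 0.3 < planted.mean()
        assert permuted.mean() < planted.mean()

    def test_species_dominates_habitat_pointwise(self, default_library):
        # habitat is a coarsening of species: the finer partition can never
        # explain less variance on the same records
        lib, _ = default_library
        sub = lib.subset(time="0h", habitat=("mesotrophic", "oligo-ombrotrophic"))
        r2_sp = band_stats.variance_explained(sub, "species").r2
        r2_hab = band_stats.variance_explained(sub, "habitat").r2
        assert np.all(r2_sp >= r2_hab - 1e-12)

    def test_unknown_factor_rejected(self, default_library):
        lib, _ = default_library
        with pytest.raises(ValueError, match="factor"):
            band_stats.variance_explained(lib, "site")


class TestGroupMeanSd:
    def test_identical_spectra_zero_sd(self, coarse_grid):
        spec = np.linspace(0.1, 0.5, len(coarse_grid))
        lib = make_library(
            coarse_grid, [spec] * 3, ["fuscum"] * 3, ["0h"] * 3, list("abc")
        )
        (mean, sd) = band_stats.group_mean_sd(lib)[("fuscum", "0h")]
        np.testing.assert_allclose(mean, spec, rtol=1e-14)
        np.testing.assert_allclose(sd, 0.0, atol=1e-15)

    def test_forced_two_sample_stats(self, coarse_grid):
        lib = make_library(
            coarse_grid,
            [np.full(len(coarse_grid), 0.2), np.full(len(coarse_grid), 0.4)],
            ["fuscum"] * 2,
            ["0h"] * 2,
            ["a", "b"],
        )
        mean, sd = band_stats.group_mean_sd(lib)[("fuscum", "0h")]
        np.testing.assert_allclose(mean, 0.3)
        np.testing.assert_allclose(sd, np.sqrt(0.02), rtol=1e-12)

    def test_planted_mean_recovered_with_noise(self, coarse_grid):
        rng = np.random.default_rng(6)
        planted = 0.3 + 0.1 * np.sin(coarse_grid.wavelengths / 40.0)
        lib = make_library(
            coarse_grid,
            [planted + 0.01 * rng.normal(size=len(coarse_grid)) for _ in range(30)],
            ["fuscum"] * 30,
            ["0h"] * 30,
            [f"s{i}" for i in range(30)],
        )
        mean, _ = band_stats.group_mean_sd(lib)[("fuscum", "0h")]
        assert np.max(np.abs(mean - planted)) < 0.01  # ~5 sigma of the mean
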