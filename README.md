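# sphagspec

Spectral-library analysis of drying boreal *Sphagnum* (peat moss)
species: reflectance-factor preprocessing, gravimetric moisture
bookkeeping, per-wavelength drying statistics, species/habitat
separability, and an exhaustive two-band Ratio-Index search for
moisture-sensitive wavelength pairs. A seeded synthetic drying-spectra
generator lets every stage run — and be tested — without downloading the
measured library.

The package is aimed at peatland remote-sensing ecologists working with
full-range (350–2500 nm) field-spectroradiometer libraries of moss
samples measured repeatedly while desiccating.

## The analysis

A spectral library holds one reflectance trace per *sample ×
measurement time* (nine species × ten replicates × {0 h, 24 h, 48 h,
1 week}) on a common 1 nm grid, plus masses weighed at every
measurement. The chain:

1. **Reflectance**: raw readings → conical–conical reflectance factor
   `CCRF = (I_s − I_dc)/(I_wr − I_dc)·RF_wr`, then Savitzky–Golay
   smoothing (25 nm window, order 2).
2. **Moisture**: `Moist % = (F_w − D_w)/F_w · 100`, with `F_w` the
   container-corrected mass at measurement time and `D_w` the dry mass.
3. **Drying contrast**: per-wavelength two-sided Wilcoxon rank-sum
   tests (fresh vs 1-week, α = 0.05) with contiguous significant
   regions; red-edge inflection points (max first derivative in
   680–750 nm) and their group contrasts.
4. **Variance decomposition**: per-wavelength R² of reflectance on
   species or habitat-group indicators (one-way SS_between/SS_total).
5. **Separability**: per-time PCA (centered, unit-scaled) and Ward
   clustering on the first three components, cut at three clusters.
6. **Ratio Index**: `RI(λ1, λ2) = R(λ1)/R(λ2)` regressed on moisture %
   for every ordered wavelength pair; R²/slope/intercept/RMSE surfaces
   and the best pair per measurement time.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

Generate a synthetic drying campaign and find the most
moisture-sensitive band pair of the 1-week spectra:

```python
from sphagspec.synthetic import SimulationConfig, generate_library
from sphagspec.preprocess import smooth_library
from sphagspec.moisture import masses_from_frame, moisture_content
from sphagspec.ratio_index import scan_all_pairs

lib, masses = generate_library(SimulationConfig(seed=42))
lib = smooth_library(lib)
moist = {m.sample_id: 100 * moisture_content(m).moist_fraction
         for m in masses_from_frame(masses) if m.measurement_time == "1week"}
scan = scan_all_pairs(lib, moist, time="1week", stride_nm=5)
print(scan.best)
```

```
(1405.0, 1360.0, -0.003814..., 0.9297..., 0.9944..., 0.00571...)
```

i.e. RI(1405 nm, 1360 nm) — two bands flanking the 1450 nm water
absorption feature — fits `RI = −0.0038·Moist% + 0.93` with R² = 0.994
and RMSE 0.006 across the 90 week-dried samples: wetter moss absorbs
more at 1405 nm relative to 1360 nm, so the ratio falls as moisture
rises.

The numbered drivers under `analysis/` run each stage and write tables
under `results/`:

```bash
python analysis/01_simulate_library.py   # 360-record synthetic campaign
python analysis/02_moisture_summary.py   # moisture bookkeeping tables
python analysis/03_band_statistics.py    # drying contrasts, REP, R2 curves
python analysis/04_pca_clustering.py     # PCA + Ward clustering
python analysis/05_ratio_index_scan.py   # exhaustive band-pair search
python analysis/06_full_pipeline.py      # all of it from one config
```

Typical output lines (seed 42): the mesotrophic species change
significantly across ~99–100 % of bands after a week of drying while
*S. cuspidatum* changes nowhere; fresh red edges sit at 717.0 nm
(mesotrophic) vs 700.8 nm (oligo-ombrotrophic), rank-sum p ≈ 1e-14;
species explain up to 95 % of fresh reflectance variance where habitat
reaches 76 %; and after a week the k = 3 clustering separates habitat
groups with purities 0.98 / 1.00 / 0.77.

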