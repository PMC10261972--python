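# Methods

This note documents the models, statistical procedures and numerical
choices behind `sphagspec`, and what the synthetic test-bed does and does
not demonstrate about measured data.

## Scientific setting

Peat mosses (*Sphagnum*) dominate the ground layer of boreal peatlands,
and the species composition of a site tracks its ecohydrology: richer,
mineral-water-fed (mesotrophic) fens and poor, rain-fed (ombrotrophic)
bogs host different species. The package analyses a laboratory drying
campaign over nine common boreal species — ten ~460 cm² samples per
species, each measured fresh (0 h) and after 24 h, 48 h and 1 week of
desiccation — asking (i) how spectra change with moisture loss, (ii)
whether species and habitat groups are spectrally separable, and (iii)
which two-band ratio best tracks gravimetric moisture.

Species → habitat-group mapping is fixed by the study design:
*S. centrale*, *S. girgensohnii*, *S. riparium* and *S. fallax* form the
mesotrophic group; *S. angustifolium*, *S. cuspidatum*, *S. fuscum* and
*S. rubellum* the oligo-ombrotrophic group; *S. capillifolium* (ecotone
collections) stays outside the division. The mapping is closed-world:
unknown species names are rejected rather than coerced.

## Reflectance preprocessing

Raw spectroradiometer readings convert to a conical–conical reflectance
factor

    CCRF(λ) = (I_s − I_dc) / (I_wr − I_dc) · RF_wr ,

with `I_s` the sample reading, `I_wr`/`I_dc` the white-reference and
dark-current readings, and `RF_wr` the panel reflectance factor (nominal
0.99 scalar by default; a per-wavelength calibration vector is accepted).
Repeated readings of one target are averaged pointwise. Each sample
reading is paired with the reference pair recorded nearest in time, ties
broken toward the earlier one; nearest-in-time is used instead of
interpolating between hourly references because it is reproducible and
assumption-free (configurable). Negative CCRF values, which occur as
noise around near-zero signal on very dark wet moss, are retained and
flagged rather than clipped — clipping would bias exactly the darkest
spectra. No detector-splice correction is applied: the analysis targets
already-processed libraries.

Spectra are smoothed with a Savitzky–Golay filter, 25 nm window
(25 points on the canonical 350–2500 nm, 1 nm grid). The polynomial
order is 2 — a common default that preserves absorption-feature shape;
both window and order are configuration parameters. Edges are handled by
refitting the polynomial on the truncated window, so polynomials up to
the filter order pass through unchanged everywhere.

## Moisture

Gravimetric moisture on a fresh-mass basis: `Moist = (F_w − D_w)/F_w`,
where `F_w` is the container-corrected sample mass at measurement time
and `D_w` the fully-dried mass, weighed once after the campaign and
shared by all measurement times of a sample. Species × time summaries
report the **mean of per-sample moistures**, not the moisture of mean
masses; the ratio is nonlinear, so the two differ whenever replicate
masses vary (only 4 of 36 published species×time rows agree under both
conventions — the low-variance, very wet *S. cuspidatum* rows among
them). Percentages are reported at one decimal. The summary's mass
column is the container-free sample mass.

## Per-wavelength statistics

*Drying contrast.* At each wavelength, fresh vs 1-week reflectance of a
species is compared with a two-sided, unpaired Wilcoxon rank-sum test at
α = 0.05. The exact null distribution is used whenever the band is
tie-free and both groups have ≤ 12 samples; otherwise the tie-corrected
normal approximation. The unpaired test is used (although the samples
are repeated measures) and no multiple-testing correction is applied
across wavelengths, both deliberate fidelity choices to the original
analysis protocol; a Benjamini–Hochberg switch exists but is off by
default. Significant wavelengths are reported as maximal contiguous
regions.

*Red-edge inflection point (REP).* The default estimator takes central
differences of the smoothed spectrum and returns the wavelength of the
maximum first derivative within 680–750 nm, ties resolved to the lowest
wavelength; a flat window raises (no inflection exists). A classical
four-point linear interpolation variant (670/700/740/780 nm) is
available. Group REP contrasts reuse the rank-sum machinery.

*Variance decomposition.* Per wavelength, reflectance is regressed on
species (all nine) or habitat-group (eight species; the excluded species
is dropped) indicators. For a categorical regressor the least-squares R²
is the one-way decomposition SS_between/SS_total, computed directly;
zero-variance wavelengths are assigned R² = 0. Because habitat is a
coarsening of species over the same records, the species curve dominates
the habitat curve pointwise — asserted as an invariant.

## Multivariate separability

PCA is computed per measurement time on centered spectra, unit-variance
scaled per wavelength by default (population sd; constant bands left at
zero), matching the default behaviour of the multivariate packages
commonly used for this analysis; covariance PCA is a flag. Components
are sign-fixed so each component's largest-magnitude loading is
positive, which makes score plots and downstream clustering
reproducible. Explained fractions are eigenvalue shares over the full
rank.

Hierarchical clustering uses Ward linkage on Euclidean distances over
the first three score columns (three components explain ≥ 90% of
variance in both the measured and synthetic libraries), and the tree is
cut at k = 3. Linkage and scaling are reproduction-sensitive: neither is
pinned by the original description, so both are explicit configuration.
Cluster composition reports contingency counts against species or
habitat plus each cluster's majority-label purity.

## Ratio-index scan

The Ratio Index of a spectrum is `RI(λ1, λ2) = R(λ1)/R(λ2)`. For the
samples of one measurement time, the RI of every ordered wavelength pair
is regressed by OLS on moisture **in percent** (slopes are then per
percentage point, matching how such models are conventionally printed);
R² is the squared Pearson correlation and RMSE uses the n denominator.
The scan is vectorized per denominator band (O(n·P) per band), computes
all four surfaces (R², slope, intercept, RMSE) over both triangles —
swapping λ1 and λ2 maps RI to 1/RI, a nonlinear transform that does not
preserve linear R², so the surface is genuinely asymmetric — and returns
the argmax pair, ties broken toward the lowest λ1 then λ2. Denominator
bands with any |R| < 1e-4 are masked: near-zero SWIR reflectance of dark
wet moss produces unstable ratios. A stride-1 scan covers all
2151 × 2151 pairs (~40 s, ~150 MB of surfaces); stride and wavelength-
range options give cheap runs. High-R² areas of the surface are
summarized as bounding boxes of 4-connected components above a
threshold.

## Synthetic campaign generator

The generator produces seeded libraries with the statistical structure
every stage assumes, so the full pipeline is testable offline. It is a
phenomenological model, deliberately not a radiative-transfer code: the
tests need controllable, invertible structure, not physical fidelity.

Per species: a baseline of a logistic red edge (inflection 698–720 nm —
mesotrophic species higher, bog species lower), a 550 nm green peak,
Gaussian pigment wells at 450/670 nm, and a linear dry-matter decline
beyond 1300 nm; a brightness scalar grading from bright fen species to
the very dark *S. cuspidatum*. Water absorption is Beer–Lambert-like,
`exp(−m·Σ depth·G(λ; c, w))` with wells at 970/1160/1450/1940 nm, so
drying (smaller moisture fraction m) releases the NIR/SWIR. Bleaching
adds a brightness gain proportional to moisture lost (dried moss turns
whitish). Replicates vary by a lognormal brightness factor **and a
smooth spectral tilt** (both scaled by one intraspecific CV, default
0.08): a flat scalar alone would cancel exactly in every band ratio,
making ratios of arbitrarily distant bands artificially noise-free,
which measured spectra do not show. Additive Gaussian measurement noise
(sd 0.0015) comes last; the noiseless model must stay inside (0, 1) or
generation fails naming the species and time.

Moisture follows exponential water-mass decay `W(t) = W0·e^(−kt)` with
habitat-dependent parameters (initial moisture / decay per day:
mesotrophic 0.895 / 0.28, oligo-ombrotrophic 0.930 / 0.055, excluded
0.900 / 0.18; *S. cuspidatum* starts at 0.987). These defaults bracket
the published species means (fresh ≈ 0.87–0.99; 1-week ≈ 0.49–0.98) and
enforce the bog-mosses-dry-slower ordering. Masses are generated by
inverting the moisture formula (constant 310 g container), so
recomputing moisture from the emitted mass table reproduces the planted
trajectories to machine precision. One global seed drives per-species
sub-streams; `planted_truth` re-derives every generating parameter for
recovery tests.

`single_well_models` is a planted-truth preset: the default species
models with the water wells replaced by a single well (default 1450 nm,
σ = 30 nm, depth 1.2). A two-band ratio is most sensitive on a well's
steepest flank (≈ one Gaussian width from the center), so the preset's
width is what bounds how far from the center the scan's best band can
legitimately land; σ = 30 nm keeps that flank within the 60 nm
localization tolerance used by the recovery test and is consistent with
the narrow 1.45 µm liquid-water feature. Recovery is assessed on the
fresh (0 h) records: their narrow moisture spread keeps the exponential
well in its linear regime, whereas over the wide 1-week spread the
linear-R² argmax migrates to the well shoulders where the response is
less saturated.

## Problem sizes and determinism

Test and analysis runs use the full 9 × 10 × 4 design (360 records,
2151 bands); ratio-index scans in the drivers and stochastic tests use
stride 5 (431 bands, ~186k pairs per time), and the multi-seed checks
use 20 seeds. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configuration yields byte-identical
pipeline outputs, and every emitted CSV carries its configuration hash.

## Known limitations

* The synthetic generator's Gaussian-well spectra cannot stand in for
  measured moss optics: passing recovery and clustering tests shows the
  *analysis machinery* behaves correctly under known structure, not that
  the published wavelengths are biologically inevitable.
* The REP estimator is a derivative-maximum stand-in; published REP
  values based on polynomial or Gaussian fits can differ by a few nm.
* The per-wavelength linear model is fit per measurement time; pooling
  times is not implemented.
* Rank-sum tests treat drying stages as independent groups (protocol
  fidelity), which understates power relative to a paired analysis.
* The exact rank-sum path requires tie-free data; heavily quantized
  reflectance falls back to the tie-corrected normal approximation.
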