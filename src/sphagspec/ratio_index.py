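"""Two-band Ratio Index (RI) search for moisture-sensitive wavelength pairs.

The Ratio Index of a spectrum is the reflectance at one wavelength divided
by the reflectance at another::

    RI(λ1, λ2) = R(λ1) / R(λ2)

For a set of samples at one drying stage, the RI of every ordered
wavelength pair is regressed (ordinary least squares) on the samples'
gravimetric moisture content in percent, ``RI = slope·Moist% + intercept``,
yielding R², slope, intercept and RMSE surfaces over (λ1, λ2); the pair
maximizing R² identifies the most moisture-sensitive band combination.
Both triangles of the surface are computed: swapping λ1 and λ2 maps
RI → 1/RI, a nonlinear transform that does not preserve linear R².

The scan is vectorized per denominator band (O(n·P) per band, O(P²)
surface memory).  Pairs whose denominator band has near-zero reflectance
in any sample (|R| below ``min_denominator``) are masked NaN — very dark,
wet moss can be close to zero in the visible and shortwave infrared, where
ratios are numerically unstable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .spectral_io import SpectralLibrary, WavelengthGrid

__all__ = [
    "RegressionFit",
    "RatioIndexScan",
    "ratio_index",
    "fit_ri_on_moisture",
    "scan_all_pairs",
    "surface_summary",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of RI on moisture % (slope per percentage point)."""

    slope: float
    intercept: float
    r2: float
    rmse: float


def ratio_index(
    spectrum: np.ndarray, grid: WavelengthGrid, l1: float, l2: float
) -> float:
    """R(λ1)/R(λ2) of one spectrum; raises if R(λ2) = 0."""
    spectrum = np.asarray(spectrum, dtype=float)
    num = spectrum[grid.index_of(l1)]
    den = spectrum[grid.index_of(l2)]
    if den == 0:
        raise ZeroDivisionError(f"reflectance at λ2 = {l2} nm is zero")
    return float(num / den)


def fit_ri_on_moisture(ri: np.ndarray, moist_pct: np.ndarray) -> RegressionFit:
    """OLS of RI (response) on moisture % (regressor).

    RMSE uses the n denominator (root of the mean squared residual).
    R² is the squared Pearson correlation; a constant RI gives slope 0,
    R² 0.  Zero moisture variance makes the slope unidentifiable and
    raises.
    """
    ri = np.asarray(ri, dtype=float)
    m = np.asarray(moist_pct, dtype=float)
    if ri.shape != m.shape or ri.ndim != 1:
        raise ValueError("ri and moist_pct must be matching 1-D arrays")
    n = ri.size
    if n < 3:
        raise ValueError("need at least 3 samples for the regression")
    mc = m - m.mean()
    smm = float(mc @ mc)
    if smm == 0:
        raise ValueError("zero variance in moisture: slope unidentifiable")
    yc = ri - ri.mean()
    syy = float(yc @ yc)
    smy = float(mc @ yc)
    slope = smy / smm
    intercept = float(ri.mean() - slope * m.mean())
    sse = syy - slope * smy
    r2 = (smy * smy) / (smm * syy) if syy > 0 else 0.0
    rmse = float(np.sqrt(max(sse, 0.0) / n))
    return RegressionFit(slope=float(slope), intercept=intercept, r2=float(r2), rmse=rmse)


@dataclass
class RatioIndexScan:
    """R²/slope/intercept/RMSE surfaces over ordered wavelength pairs.

    Surfaces are indexed ``[i, j]`` = (λ1 = wavelengths[i], λ2 =
    wavelengths[j]); masked pairs are NaN.  ``best`` is the
    (λ1, λ2, slope, intercept, r2, rmse) tuple at the R² argmax, ties
    broken toward the lowest λ1 then lowest λ2.
    """

    wavelengths: np.ndarray
    time: str | None
    r2_surface: np.ndarray
    slope_surface: np.ndarray
    intercept_surface: np.ndarray
    rmse_surface: np.ndarray
    n_samples: int

    @property
    def best(self) -> tuple[float, float, float, float, float, float]:
        if np.all(np.isnan(self.r2_surface)):
            raise ValueError("entire surface is masked")
        top = np.nanmax(self.r2_surface)
        # Row-major order of the first maximal entry = lowest λ1, then λ2.
        i, j = np.unravel_index(
            int(np.argmax(self.r2_surface == top)), self.r2_surface.shape
        )
        return (
            float(self.wavelengths[i]),
            float(self.wavelengths[j]),
            float(self.slope_surface[i, j]),
            float(self.intercept_surface[i, j]),
            float(self.r2_surface[i, j]),
            float(self.rmse_surface[i, j]),
        )


def scan_all_pairs(
    lib: SpectralLibrary,
    moist_pct: dict[str, float] | np.ndarray,
    time: str | None = None,
    stride_nm: int = 1,
    wavelength_range: tuple[float, float] | None = None,
    min_denominator: float = 1e-4,
) -> RatioIndexScan:
    """Exhaustive RI regression scan over all ordered wavelength pairs.

    Parameters
    ----------
    lib
        Spectral library; if ``time`` is given, only that measurement time
        is scanned.
    moist_pct
        Moisture content in percent per sample: either a mapping
        ``sample_id → %`` or an array aligned with the (subset) records.
    stride_nm
        Band subsampling step in grid points (1 = all 2151 bands →
        ~4.6 million pairs).
    wavelength_range
        Optional (lo, hi) restriction of both axes.
    min_denominator
        Denominator bands where any sample's |R| falls below this are
        masked (unstable ratios on near-zero reflectance).
    """
    sub = lib.subset(time=time) if time is not None else lib
    x = sub.reflectance
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need ≥3 samples at time {time!r}, have {n}")
    if isinstance(moist_pct, dict):
        try:
            m = np.array([moist_pct[meta.sample_id] for meta in sub.meta], dtype=float)
        except KeyError as e:
            raise KeyError(f"no moisture value for sample {e.args[0]!r}") from None
    else:
        m = np.asarray(moist_pct, dtype=float)
        if m.shape != (n,):
            raise ValueError("moisture vector does not align with the records")

    w = sub.grid.wavelengths
    keep = np.ones(w.size, dtype=bool)
    if wavelength_range is not None:
        keep &= (w >= wavelength_range[0]) & (w <= wavelength_range[1])
    idx = np.flatnonzero(keep)[:: max(int(stride_nm), 1)]
    w = w[idx]
    x = x[:, idx]
    p = w.size

    mc = m - m.mean()
    smm = float(mc @ mc)
    if smm == 0:
        raise ValueError("zero variance in moisture: slope unidentifiable")

    r2 = np.empty((p, p))
    slope = np.empty((p, p))
    intercept = np.empty((p, p))
    rmse = np.empty((p, p))
    bad_den = np.abs(x).min(axis=0) < min_denominator

    for j in range(p):
        if bad_den[j]:
            r2[:, j] = slope[:, j] = intercept[:, j] = rmse[:, j] = np.nan
            continue
        y = x / x[:, j][:, None]  # n × p: RI of every λ1 against this λ2
        ym = y.mean(axis=0)
        yc = y - ym
        syy = np.einsum("ij,ij->j", yc, yc)
        smy = mc @ yc
        with np.errstate(invalid="ignore", divide="ignore"):
            sl = smy / smm
            r2c = np.where(syy > 0, (smy * smy) / (smm * syy), 0.0)
        sse = np.maximum(syy - sl * smy, 0.0)
        r2[:, j] = r2c
        slope[:, j] = sl
        intercept[:, j] = ym - sl * m.mean()
        rmse[:, j] = np.sqrt(sse / n)

    return RatioIndexScan(
        wavelengths=w,
        time=time,
        r2_surface=r2,
        slope_surface=slope,
        intercept_surface=intercept,
        rmse_surface=rmse,
        n_samples=n,
    )


@dataclass(frozen=True)
class SurfaceRegion:
    """Bounding box of one connected high-R² region of the scan surface."""

    l1_start_nm: float
    l1_end_nm: float
    l2_start_nm: float
    l2_end_nm: float
    n_pairs: int
    max_r2: float


def surface_summary(s: RatioIndexScan, r2_threshold: float = 0.7) -> list[SurfaceRegion]:
    """Connected components of ``r2 > threshold``, as bounding boxes.

    Connectivity is 4-neighbour on the (λ1, λ2) lattice; masked (NaN)
    pairs never belong to a region.  Returns an empty list when nothing
    exceeds the threshold.
    """
    mask = np.nan_to_num(s.r2_surface, nan=-np.inf) > r2_threshold
    labeled, n_regions = ndimage.label(mask)
    out = []
    for sl1, sl2 in ndimage.find_objects(labeled):
        block = s.r2_surface[sl1, sl2]
        region_mask = mask[sl1, sl2]
        out.append(
            SurfaceRegion(
                l1_start_nm=float(s.wavelengths[sl1.start]),
                l1_end_nm=float(s.wavelengths[sl1.stop - 1]),
                l2_start_nm=float(s.wavelengths[sl2.start]),
                l2_end_nm=float(s.wavelengths[sl2.stop - 1]),
                n_pairs=int(region_mask.sum()),
                max_r2=float(np.nanmax(np.where(region_mask, block, np.nan))),
            )
        )
    return out
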