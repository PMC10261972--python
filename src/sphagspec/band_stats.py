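"""Per-wavelength group statistics for spectral libraries.

Covers the univariate analysis chain of the drying experiment:

* mean ± sd spectra per group (species × measurement time);
* per-wavelength two-sided Wilcoxon rank-sum tests between two drying
  stages of one species, with contiguous significant regions;
* red-edge inflection point (REP) extraction and between-group REP tests;
* per-wavelength coefficient of determination (R²) of reflectance
  regressed on a categorical factor (species or habitat group).

Rank-sum p-values use the exact null distribution whenever the band has no
ties and both groups have ≤ 12 samples, and the tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spectral_io import SpectralLibrary, WavelengthGrid, habitat_group

__all__ = [
    "SignificanceMask",
    "REPResult",
    "VarianceCurve",
    "rank_sum_test",
    "group_mean_sd",
    "wilcoxon_bands",
    "compute_rep",
    "rep_library",
    "rep_group_test",
    "variance_explained",
]

_EXACT_MAX_N = 12


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact distribution for tie-free samples with both sizes ≤ 12; normal
    approximation with tie correction otherwise.  Degenerate comparisons
    (all pooled values identical) return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = (
        "exact"
        if not has_ties and max(x.size, y.size) <= _EXACT_MAX_N
        else "asymptotic"
    )
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


@dataclass
class SignificanceMask:
    """Per-wavelength p-values with the α-thresholded significant regions."""

    grid: WavelengthGrid
    p_values: np.ndarray
    alpha: float = 0.05
    significant: np.ndarray = field(init=False)
    regions: list[tuple[float, float]] = field(init=False)

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.p_values.shape != (len(self.grid),):
            raise ValueError("p-value vector does not match the grid")
        self.significant = self.p_values < self.alpha
        self.regions = _runs_to_regions(self.significant, self.grid)


def _runs_to_regions(
    mask: np.ndarray, grid: WavelengthGrid
) -> list[tuple[float, float]]:
    """Maximal runs of True as inclusive [start_nm, end_nm] intervals."""
    w = grid.wavelengths
    padded = np.concatenate([[False], mask, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    return [(float(w[s]), float(w[e])) for s, e in zip(starts, ends)]


def group_mean_sd(
    lib: SpectralLibrary, by: tuple[str, ...] = ("species", "measurement_time")
) -> dict[tuple, tuple[np.ndarray, np.ndarray]]:
    """Pointwise mean and sample sd (n−1) spectra per metadata group.

    ``by`` names SampleMeta fields; keys of the result are tuples of their
    values.  Groups of size one get sd = 0.
    """
    keys = [tuple(getattr(m, f) for f in by) for m in lib.meta]
    out: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for key in dict.fromkeys(keys):  # preserves first-seen order
        idx = [i for i, k in enumerate(keys) if k == key]
        block = lib.reflectance[idx]
        sd = block.std(axis=0, ddof=1) if len(idx) > 1 else np.zeros(block.shape[1])
        out[key] = (block.mean(axis=0), sd)
    return out


def wilcoxon_bands(
    lib: SpectralLibrary,
    species: str,
    time_a: str = "0h",
    time_b: str = "1week",
    alpha: float = 0.05,
) -> SignificanceMask:
    """Band-by-band rank-sum comparison of two drying stages of one species.

    Tests, at every wavelength, whether reflectance of the ``time_a``
    samples differs from the ``time_b`` samples (two-sided, unpaired).
    """
    a = lib.subset(species=species, time=time_a).reflectance
    b = lib.subset(species=species, time=time_b).reflectance
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need ≥2 samples of {species} at both {time_a} and {time_b}"
        )
    p = np.array([rank_sum_test(a[:, j], b[:, j]) for j in range(a.shape[1])])
    return SignificanceMask(lib.grid, p, alpha=alpha)


@dataclass(frozen=True)
class REPResult:
    """Red-edge inflection point of one spectrum."""

    rep_nm: float
    search_window: tuple[float, float] = (680.0, 750.0)
    method: str = "max_first_derivative"


def compute_rep(
    spectrum: np.ndarray,
    grid: WavelengthGrid,
    window: tuple[float, float] = (680.0, 750.0),
    method: str = "max_first_derivative",
) -> REPResult:
    """Red-edge inflection point: steepest reflectance rise in ``window``.

    ``max_first_derivative`` (default) takes central differences of the
    (already smoothed) spectrum and returns the wavelength of the maximum
    within the window, ties resolved to the lowest wavelength.  The
    ``linear_four_point`` alternative interpolates the red-edge midpoint
    between 700 and 740 nm from reflectance at 670/700/740/780 nm.
    A spectrum that is flat across the window has no inflection point and
    raises.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (len(grid),):
        raise ValueError("spectrum does not match the grid")
    lo, hi = window
    w = grid.wavelengths
    in_win = (w >= lo) & (w <= hi)
    if np.ptp(spectrum[in_win]) == 0:
        raise ValueError("flat spectrum in the red-edge window: REP undefined")

    if method == "max_first_derivative":
        deriv = np.gradient(spectrum, w)  # central differences, one-sided ends
        deriv_win = np.where(in_win, deriv, -np.inf)
        idx = int(np.argmax(deriv_win))  # argmax takes the first (lowest λ) tie
        rep = float(w[idx])
    elif method == "linear_four_point":
        r670, r700, r740, r780 = (
            spectrum[grid.index_of(nm)] for nm in (670, 700, 740, 780)
        )
        r_edge = (r670 + r780) / 2.0
        if r740 == r700:
            raise ValueError("degenerate red edge: R(740) == R(700)")
        rep = 700.0 + 40.0 * (r_edge - r700) / (r740 - r700)
    else:
        raise ValueError(f"unknown REP method {method!r}")
    return REPResult(rep_nm=rep, search_window=window, method=method)


def rep_library(
    lib: SpectralLibrary,
    window: tuple[float, float] = (680.0, 750.0),
    method: str = "max_first_derivative",
) -> pd.DataFrame:
    """REP of every record: columns sample_id, species, time, rep_nm."""
    rows = [
        {
            "sample_id": m.sample_id,
            "species": m.species,
            "measurement_time": m.measurement_time,
            "rep_nm": compute_rep(r, lib.grid, window, method).rep_nm,
        }
        for m, r in lib
    ]
    return pd.DataFrame(rows)


def rep_group_test(
    reps_a: list[REPResult] | np.ndarray, reps_b: list[REPResult] | np.ndarray
) -> float:
    """Two-sided rank-sum p-value comparing two groups of REP positions."""

    def _values(reps):
        return np.array(
            [r.rep_nm if isinstance(r, REPResult) else float(r) for r in reps]
        )

    a, b = _values(reps_a), _values(reps_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need ≥2 REP values per group")
    return rank_sum_test(a, b)


@dataclass
class VarianceCurve:
    """Per-wavelength R² of reflectance on a categorical factor."""

    grid: WavelengthGrid
    r2: np.ndarray
    factor: str

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        if self.r2.shape != (len(self.grid),):
            raise ValueError("R² vector does not match the grid")


def variance_explained(lib: SpectralLibrary, factor: str) -> VarianceCurve:
    """R² of the least-squares fit of reflectance on factor indicators.

    For a categorical regressor this is the one-way decomposition
    SS_between / SS_total at each wavelength.  ``factor`` is ``"species"``
    (all nine) or ``"habitat"`` (records of the two habitat groups only;
    the species outside the division is dropped).  Wavelengths with zero
    total variance get R² = 0.  Pass a single-time subset of the library to
    analyse one drying stage.
    """
    if factor == "species":
        sub = lib
        labels = np.array([m.species for m in sub.meta])
    elif factor == "habitat":
        sub = lib.subset(habitat=("mesotrophic", "oligo-ombrotrophic"))
        labels = np.array([m.habitat_group for m in sub.meta])
    else:
        raise ValueError(f"factor must be 'species' or 'habitat', got {factor!r}")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two factor levels")

    x = sub.reflectance
    grand = x.mean(axis=0)
    sst = ((x - grand) ** 2).sum(axis=0)
    ssb = np.zeros_like(grand)
    for lv in np.unique(labels):
        block = x[labels == lv]
        ssb += len(block) * (block.mean(axis=0) - grand) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, ssb / sst, 0.0)
    return VarianceCurve(sub.grid, np.clip(r2, 0.0, 1.0), factor)
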