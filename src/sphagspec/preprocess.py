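"""Raw-reading preprocessing: reflectance factors and spectral smoothing.

Laboratory reflectance of a sample under fixed conical illumination and
view geometry is expressed as a conical–conical reflectance factor (CCRF):
the dark-current-corrected sample reading ratioed to the dark-current-
corrected reading of a calibrated white reference panel, scaled by the
panel's own reflectance factor::

    CCRF = (I_s - I_dc) / (I_wr - I_dc) * RF_wr

White-reference / dark-current pairs are recorded periodically during a
measurement session; each sample reading is paired with the reference
nearest in time.  Reflectance spectra are then smoothed with a
Savitzky–Golay filter (default 25 nm window, quadratic polynomial).

Negative CCRF values can occur at near-zero signal (very dark, wet moss in
the visible and shortwave infrared) and are retained, not clipped; use
:func:`negative_mask` for QC flagging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .spectral_io import SpectralLibrary, WavelengthGrid

__all__ = [
    "RawRadianceTriplet",
    "SmoothingConfig",
    "average_repetitions",
    "compute_ccrf",
    "select_reference",
    "smooth",
    "smooth_library",
    "negative_mask",
]


@dataclass
class RawRadianceTriplet:
    """Sample / white-reference / dark-current digital readings on one grid.

    ``rf_wr`` is the panel reflectance factor — the nominal 0.99 scalar of a
    calibrated Spectralon panel, or a per-wavelength calibration vector.
    Timestamps ``t_s``/``t_wr`` are in minutes from session start (any
    consistent unit works).
    """

    i_s: np.ndarray
    i_wr: np.ndarray
    i_dc: np.ndarray
    rf_wr: float | np.ndarray = 0.99
    t_s: float = 0.0
    t_wr: float = 0.0

    def __post_init__(self) -> None:
        self.i_s = np.asarray(self.i_s, dtype=float)
        self.i_wr = np.asarray(self.i_wr, dtype=float)
        self.i_dc = np.asarray(self.i_dc, dtype=float)
        if not (self.i_s.shape == self.i_wr.shape == self.i_dc.shape):
            raise ValueError("sample, reference and dark readings must share one grid")


def average_repetitions(readings: Sequence[np.ndarray]) -> np.ndarray:
    """Pointwise arithmetic mean of repeated readings of one target."""
    if len(readings) == 0:
        raise ValueError("no readings to average")
    stack = np.asarray(readings, dtype=float)
    if stack.ndim != 2:
        raise ValueError("readings must be equal-length vectors")
    return stack.mean(axis=0)


def compute_ccrf(t: RawRadianceTriplet) -> np.ndarray:
    """Conical–conical reflectance factor of one sample reading.

    Raises if the reference signal equals the dark current anywhere
    (zero denominator); negative outputs are allowed and left unclipped.
    """
    denom = t.i_wr - t.i_dc
    if np.any(denom == 0):
        bad = int(np.flatnonzero(denom == 0)[0])
        raise ZeroDivisionError(
            f"white reference equals dark current at band index {bad}"
        )
    return (t.i_s - t.i_dc) / denom * t.rf_wr


def negative_mask(spectrum: np.ndarray) -> np.ndarray:
    """QC flag: True where a reflectance value is negative."""
    return np.asarray(spectrum) < 0


def select_reference(
    t_s: float, refs: Sequence[tuple[float, np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the (I_wr, I_dc) pair recorded nearest in time to ``t_s``.

    Ties break toward the earlier reference.  ``refs`` holds
    ``(timestamp, i_wr, i_dc)`` tuples in any order.
    """
    if len(refs) == 0:
        raise ValueError("no reference measurements available")
    ordered = sorted(refs, key=lambda r: r[0])
    best = min(ordered, key=lambda r: abs(r[0] - t_s))  # min is stable: earlier wins ties
    return best[1], best[2]


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky–Golay smoothing parameters.

    ``window_nm`` is converted to grid points (must come out odd);
    ``polyorder`` must be smaller than the window length.
    """

    window_nm: float = 25.0
    polyorder: int = 2

    def window_points(self, grid: WavelengthGrid) -> int:
        pts = int(round(self.window_nm / grid.step_nm))
        if pts % 2 == 0:
            raise ValueError(
                f"{self.window_nm} nm window is {pts} grid points; must be odd"
            )
        if self.polyorder >= pts:
            raise ValueError("polyorder must be smaller than the window length")
        return pts


def smooth(
    spectrum: np.ndarray,
    cfg: SmoothingConfig = SmoothingConfig(),
    grid: WavelengthGrid | None = None,
) -> np.ndarray:
    """Savitzky–Golay filter one spectrum (or a stack, last axis = bands).

    Edges are handled by refitting the polynomial on the truncated window
    (``mode="interp"``), so a polynomial of degree ≤ ``polyorder`` passes
    through unchanged everywhere including the ends.
    """
    grid = grid or WavelengthGrid()
    spectrum = np.asarray(spectrum, dtype=float)
    window = cfg.window_points(grid)
    if spectrum.shape[-1] < window:
        raise ValueError(
            f"spectrum has {spectrum.shape[-1]} points, shorter than the "
            f"{window}-point window"
        )
    return savgol_filter(spectrum, window, cfg.polyorder, axis=-1, mode="interp")


def smooth_library(lib: SpectralLibrary, cfg: SmoothingConfig = SmoothingConfig()) -> SpectralLibrary:
    """Smooth every record of a library; metadata and grid are unchanged."""
    return SpectralLibrary(lib.grid, lib.meta, smooth(lib.reflectance, cfg, lib.grid))
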