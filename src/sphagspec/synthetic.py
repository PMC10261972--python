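"""Seeded synthetic drying-spectra generator.

Emulates the statistical structure of a laboratory drying campaign over
boreal *Sphagnum* mosses — nine species × ten replicates measured fresh
and after 24 h, 48 h and 1 week of desiccation — so that every analysis
stage is testable without downloading the measured library.

The spectral model is phenomenological, not a radiative-transfer code:

* a species baseline built from a logistic red edge between a visible
  level and a NIR plateau, a green reflectance peak (550 nm), Gaussian
  pigment absorption wells (450 and 670 nm) and a linear dry-matter
  decline beyond 1300 nm;
* Beer–Lambert-like water absorption, ``exp(-m · Σ depth·G(λ; c, w))``
  with Gaussian wells at 970, 1160, 1450 and 1940 nm whose strength scales
  with the current moisture fraction ``m`` — drying releases the SWIR;
* bleaching: a brightness gain proportional to moisture lost, mirroring
  how dried moss turns whitish;
* replicate-level multiplicative (lognormal) brightness variation plus a
  smooth spectral tilt — replicates of one species differ in shape, not
  only in scale, so band ratios over distant wavelengths are noisier than
  ratios of neighbouring bands, as in measured spectra — and additive
  measurement noise.

Moisture follows an exponential water-mass decay ``W(t) = W0·e^(−kt)``
with habitat-dependent rates: mosses of wet, nutrient-poor bog habitats
(dense, water-retaining) dry far slower than mosses of richer fen
habitats.  Masses are generated by inverting the gravimetric moisture
formula, so recomputing moisture from the emitted mass table reproduces
the planted trajectories exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .spectral_io import (
    DEFAULT_GRID,
    MEASUREMENT_TIMES,
    SPECIES,
    SPECIES_CODES,
    SampleMeta,
    SpectralLibrary,
    WavelengthGrid,
    habitat_group,
)

__all__ = [
    "SpeciesSpectralModel",
    "DryingModel",
    "SimulationConfig",
    "default_species_models",
    "single_well_models",
    "generate_library",
    "planted_truth",
]

_TIME_DAYS = {"0h": 0.0, "24h": 1.0, "48h": 2.0, "1week": 7.0}


@dataclass(frozen=True)
class SpeciesSpectralModel:
    """Parameters of one species' phenomenological reflectance model.

    Depths and levels are unitless reflectance; wavelengths in nm.
    ``water_wells`` holds (center_nm, width_nm, depth) triplets; the depth
    applies at moisture fraction 1 and scales linearly with moisture.
    """

    species: str
    vis_level: float
    nir_plateau: float
    red_edge_nm: float
    red_edge_width_nm: float
    green_peak: float
    pigment_450: float
    pigment_670: float
    swir_decline: float
    brightness: float
    water_wells: tuple[tuple[float, float, float], ...] = (
        (970.0, 45.0, 0.35),
        (1160.0, 55.0, 0.55),
        (1450.0, 80.0, 1.8),
        (1940.0, 110.0, 2.6),
    )

    def __post_init__(self) -> None:
        if not 680.0 <= self.red_edge_nm <= 750.0:
            raise ValueError("red-edge inflection must lie in [680, 750] nm")


# vis, nir, red-edge λ/width, green peak, pigment depths, SWIR decline,
# brightness — mesotrophic species bright with high red edges, ombrotrophic
# species dark (cuspidatum darkest) with low red edges.
_SPECIES_PARAMS: dict[str, tuple] = {
    "centrale": (0.055, 0.50, 718, 14, 0.030, 0.015, 0.020, 0.34, 1.00),
    "girgensohnii": (0.050, 0.47, 715, 13, 0.028, 0.014, 0.019, 0.33, 0.95),
    "riparium": (0.060, 0.52, 720, 15, 0.032, 0.016, 0.021, 0.35, 1.05),
    "capillifolium": (0.050, 0.45, 710, 13, 0.027, 0.014, 0.018, 0.33, 0.88),
    "fallax": (0.055, 0.49, 716, 14, 0.030, 0.015, 0.020, 0.34, 1.02),
    "angustifolium": (0.048, 0.44, 704, 12, 0.026, 0.013, 0.018, 0.32, 0.85),
    "cuspidatum": (0.038, 0.36, 698, 11, 0.020, 0.010, 0.014, 0.30, 0.48),
    "fuscum": (0.045, 0.42, 702, 12, 0.024, 0.012, 0.016, 0.31, 0.72),
    "rubellum": (0.047, 0.43, 703, 12, 0.025, 0.013, 0.017, 0.31, 0.70),
}

#: Mean dry mass (g) per species, used to anchor the mass bookkeeping.
_DRY_MASS_G = {
    "centrale": 43.3,
    "girgensohnii": 47.6,
    "riparium": 46.2,
    "capillifolium": 60.8,
    "fallax": 48.3,
    "angustifolium": 72.2,
    "cuspidatum": 35.1,
    "fuscum": 81.7,
    "rubellum": 88.3,
}


def default_species_models() -> dict[str, SpeciesSpectralModel]:
    """The nine default species models (habitat-graded brightness/red edge)."""
    return {
        sp: SpeciesSpectralModel(sp, *params)
        for sp, params in _SPECIES_PARAMS.items()
    }


def single_well_models(
    center_nm: float = 1450.0, width_nm: float = 30.0, depth: float = 1.2
) -> dict[str, SpeciesSpectralModel]:
    """Default models with a single moisture-scaled well at ``center_nm``.

    Used for planted-truth recovery experiments where the scan's best band
    must be attributable to one known absorption center.  The default
    width matches the narrow 1.45 µm liquid-water feature; because a
    ratio of nearby bands is most moisture-sensitive on the well's
    steepest flank (≈ one Gaussian width from the center), the width also
    bounds how far from the center the scan's best band can legitimately
    land.
    """
    return {
        sp: replace(m, water_wells=((center_nm, width_nm, depth),))
        for sp, m in default_species_models().items()
    }


@dataclass(frozen=True)
class DryingModel:
    """Habitat-dependent desiccation dynamics.

    ``habitat_params`` maps habitat group → (initial moisture fraction,
    water-mass decay rate per day).  Bog (oligo-ombrotrophic) mosses
    retain water far better than fen (mesotrophic) mosses, so their decay
    rate must be smaller.  ``species_m0`` overrides the initial moisture
    of individual species.  ``bleach_coef`` converts moisture loss into a
    relative reflectance gain (whitening of dried moss).
    """

    habitat_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mesotrophic": (0.895, 0.28),
            "oligo-ombrotrophic": (0.930, 0.055),
            "excluded": (0.900, 0.18),
        }
    )
    species_m0: dict[str, float] = field(
        default_factory=lambda: {"cuspidatum": 0.987}
    )
    bleach_coef: float = 0.8

    def __post_init__(self) -> None:
        meso = self.habitat_params["mesotrophic"][1]
        ombro = self.habitat_params["oligo-ombrotrophic"][1]
        if not ombro < meso:
            raise ValueError(
                "oligo-ombrotrophic decay rate must be below the mesotrophic rate"
            )

    def initial_moisture(self, species: str) -> float:
        if species in self.species_m0:
            return self.species_m0[species]
        return self.habitat_params[habitat_group(species)][0]

    def decay_per_day(self, species: str) -> float:
        return self.habitat_params[habitat_group(species)][1]


@dataclass(frozen=True)
class SimulationConfig:
    """Design and noise parameters of one synthetic campaign."""

    n_species: int = 9
    n_replicates: int = 10
    times: tuple[str, ...] = MEASUREMENT_TIMES
    seed: int = 0
    intraspecific_cv: float = 0.08
    noise_sd: float = 0.0015
    grid: WavelengthGrid = DEFAULT_GRID
    container_mass_g: float = 310.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_species <= len(SPECIES):
            raise ValueError(f"n_species must be in 1..{len(SPECIES)}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be ≥ 1")
        unknown = set(self.times) - set(MEASUREMENT_TIMES)
        if unknown:
            raise ValueError(f"unknown measurement times {sorted(unknown)}")


def _baseline(model: SpeciesSpectralModel, lam: np.ndarray) -> np.ndarray:
    def g(c, w):
        return np.exp(-0.5 * ((lam - c) / w) ** 2)

    base = model.vis_level + (model.nir_plateau - model.vis_level) * expit(
        (lam - model.red_edge_nm) / model.red_edge_width_nm
    )
    base = base + model.green_peak * g(550.0, 30.0)
    base = base - model.pigment_450 * g(450.0, 40.0) - model.pigment_670 * g(670.0, 30.0)
    base = base * (1.0 - model.swir_decline * np.clip((lam - 1300.0) / 1200.0, 0.0, None))
    return base


def _water_absorbance(model: SpeciesSpectralModel, lam: np.ndarray) -> np.ndarray:
    absorb = np.zeros_like(lam, dtype=float)
    for center, width, depth in model.water_wells:
        absorb += depth * np.exp(-0.5 * ((lam - center) / width) ** 2)
    return absorb


def _simulate(
    cfg: SimulationConfig,
    models: dict[str, SpeciesSpectralModel] | None,
    drying: DryingModel | None,
):
    models = models if models is not None else default_species_models()
    drying = drying if drying is not None else DryingModel()
    species = SPECIES[: cfg.n_species]
    lam = cfg.grid.wavelengths
    cv = cfg.intraspecific_cv

    meta: list[SampleMeta] = []
    spectra: list[np.ndarray] = []
    mass_rows: list[dict] = []
    truth_moist: dict[str, float] = {}

    streams = np.random.SeedSequence(cfg.seed).spawn(len(species))
    for sp, stream in zip(species, streams):
        model = models[sp]
        rng = np.random.default_rng(stream)
        m0 = drying.initial_moisture(sp)
        k = drying.decay_per_day(sp)
        baseline = _baseline(model, lam)
        absorbance = _water_absorbance(model, lam)

        for rep in range(cfg.n_replicates):
            sample_id = f"{SPECIES_CODES[sp]}_{rep + 1:02d}"
            # Replicate-level intraspecific variation, all scaled by one CV
            # so a zero-CV run yields identical replicates.
            bright = model.brightness * np.exp(cv * rng.standard_normal())
            # Smooth shape variation: a linear tilt across the spectrum,
            # zero-mean at mid-range; decorrelates distant bands within a
            # replicate while leaving neighbouring bands locked together.
            tilt = 2.0 * cv * rng.standard_normal()
            tilt_curve = 1.0 + tilt * (lam - 1425.0) / 1075.0
            dry_mass = _DRY_MASS_G[sp] * np.exp(1.5 * cv * rng.standard_normal())
            w0 = dry_mass * m0 / (1.0 - m0) * np.exp(
                2.0 * cv * rng.standard_normal()
            )
            k_i = k * np.exp(1.5 * cv * rng.standard_normal())
            m0_i = w0 / (w0 + dry_mass)

            for time in cfg.times:
                water = w0 * np.exp(-k_i * _TIME_DAYS[time])
                m = water / (water + dry_mass)
                clean = (
                    baseline
                    * np.exp(-m * absorbance)
                    * bright
                    * tilt_curve
                    * (1.0 + drying.bleach_coef * (m0_i - m))
                )
                if clean.min() <= 0.0 or clean.max() >= 1.0:
                    raise ValueError(
                        f"model for {sp} at {time} produced reflectance outside "
                        f"(0, 1): range [{clean.min():.4f}, {clean.max():.4f}]"
                    )
                refl = clean + cfg.noise_sd * rng.standard_normal(lam.size)
                meta.append(
                    SampleMeta(sample_id=sample_id, species=sp, measurement_time=time)
                )
                spectra.append(refl)
                fresh = water + dry_mass
                mass_rows.append(
                    {
                        "sample_id": sample_id,
                        "measurement_time": time,
                        "total_mass_g": fresh + cfg.container_mass_g,
                        "container_mass_g": cfg.container_mass_g,
                        "dry_mass_g": dry_mass,
                    }
                )
                truth_moist[f"{sample_id}_{time}"] = float(m)

    lib = SpectralLibrary(cfg.grid, meta, np.array(spectra))
    masses = pd.DataFrame(mass_rows)
    truth = {
        "moisture": truth_moist,
        "habitat": {sp: habitat_group(sp) for sp in species},
        "well_centers": {
            sp: tuple(c for c, _, _ in models[sp].water_wells) for sp in species
        },
        "red_edge_nm": {sp: models[sp].red_edge_nm for sp in species},
        "initial_moisture": {sp: drying.initial_moisture(sp) for sp in species},
        "decay_per_day": {sp: drying.decay_per_day(sp) for sp in species},
    }
    return lib, masses, truth


def generate_library(
    cfg: SimulationConfig = SimulationConfig(),
    models: dict[str, SpeciesSpectralModel] | None = None,
    drying: DryingModel | None = None,
) -> tuple[SpectralLibrary, pd.DataFrame]:
    """Generate a seeded synthetic library and its mass table.

    Deterministic given ``cfg.seed`` (per-species sub-streams).  Returns
    the library plus a mass table in the canonical masses-CSV layout;
    applying the gravimetric moisture formula to the masses reproduces the
    planted moisture fractions exactly.
    """
    lib, masses, _ = _simulate(cfg, models, drying)
    return lib, masses


def planted_truth(
    cfg: SimulationConfig = SimulationConfig(),
    models: dict[str, SpeciesSpectralModel] | None = None,
    drying: DryingModel | None = None,
) -> dict:
    """Generating parameters of the library ``generate_library`` would emit.

    Keys: ``moisture`` (record id → true moisture fraction), ``habitat``,
    ``well_centers``, ``red_edge_nm``, ``initial_moisture``,
    ``decay_per_day``.
    """
    _, _, truth = _simulate(cfg, models, drying)
    return truth
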