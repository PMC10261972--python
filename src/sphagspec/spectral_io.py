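"""Spectral-library container and plain-text I/O.

A spectral library couples a common wavelength grid with one reflectance
trace per *record* (one sample measured at one drying stage) and per-record
metadata.  Libraries are exchanged as a pair of CSV files:

* a **wide spectra CSV** — rows are wavelengths (column ``wavelength_nm``),
  one column per record id;
* a **metadata CSV** keyed by ``sample_id`` + ``measurement_time``.

Record ids follow the convention ``<species_code>_<replicate>_<time>``
(e.g. ``cus_03_1week``); the sample id is the record id without the time
suffix.  The canonical grid is 350–2500 nm at 1 nm (2151 bands), the range
of a full-range field spectroradiometer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SampleMeta",
    "SpectralLibrary",
    "DEFAULT_GRID",
    "SPECIES",
    "SPECIES_CODES",
    "MEASUREMENT_TIMES",
    "NUTRIENT_LEVELS",
    "habitat_group",
    "read_library",
    "write_library",
    "resample_to_grid",
]

#: The nine study species (epithets of the *Sphagnum* genus).
SPECIES = (
    "centrale",
    "girgensohnii",
    "riparium",
    "capillifolium",
    "fallax",
    "angustifolium",
    "cuspidatum",
    "fuscum",
    "rubellum",
)

#: Three-letter codes used in record ids.
SPECIES_CODES = {
    "centrale": "cen",
    "girgensohnii": "gir",
    "riparium": "rip",
    "capillifolium": "cap",
    "fallax": "fal",
    "angustifolium": "ang",
    "cuspidatum": "cus",
    "fuscum": "fus",
    "rubellum": "rub",
}
CODES_TO_SPECIES = {v: k for k, v in SPECIES_CODES.items()}

#: Drying stages at which each sample was measured.
MEASUREMENT_TIMES = ("0h", "24h", "48h", "1week")

#: Nutrient status of each species' habitat, richest to poorest.
NUTRIENT_LEVELS = {
    "centrale": "mesotrophic",
    "girgensohnii": "mesotrophic",
    "riparium": "mesotrophic",
    "fallax": "oligo-mesotrophic",
    "capillifolium": "ombro-oligotrophic",
    "angustifolium": "ombro-minerophic",
    "cuspidatum": "ombro-oligotrophic",
    "rubellum": "ombrotrophic",
    "fuscum": "ombrotrophic",
}

# Two-way habitat division: the mesotrophic group pools the three
# mesotrophic species with the intermediate fallax; the oligo-ombrotrophic
# group pools the three bog species with the oligotrophic angustifolium.
# capillifolium (ecotone collections) stays outside the division.
_HABITAT_GROUPS = {
    "centrale": "mesotrophic",
    "girgensohnii": "mesotrophic",
    "riparium": "mesotrophic",
    "fallax": "mesotrophic",
    "angustifolium": "oligo-ombrotrophic",
    "cuspidatum": "oligo-ombrotrophic",
    "fuscum": "oligo-ombrotrophic",
    "rubellum": "oligo-ombrotrophic",
    "capillifolium": "excluded",
}


def habitat_group(species: str) -> str:
    """Habitat group of a study species (closed-world: unknown names raise).

    Returns one of ``"mesotrophic"``, ``"oligo-ombrotrophic"`` or
    ``"excluded"``.
    """
    try:
        return _HABITAT_GROUPS[species]
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}; expected one of {sorted(_HABITAT_GROUPS)}"
        ) from None


@dataclass(frozen=True)
class WavelengthGrid:
    """Regular wavelength grid in nanometres (inclusive of both ends)."""

    start_nm: float = 350.0
    end_nm: float = 2500.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        for f in ("start_nm", "end_nm", "step_nm"):
            object.__setattr__(self, f, float(getattr(self, f)))
        if self.step_nm <= 0 or self.end_nm <= self.start_nm:
            raise ValueError("grid must be strictly increasing")
        n = (self.end_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step does not divide the grid range evenly")

    def __len__(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(len(self))

    def index_of(self, nm: float) -> int:
        """Index of a wavelength on the grid; raises if off-grid."""
        pos = (nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if abs(pos - idx) > 1e-9 or not 0 <= idx < len(self):
            raise ValueError(f"{nm} nm is not on the grid")
        return idx


DEFAULT_GRID = WavelengthGrid()


@dataclass(frozen=True)
class SampleMeta:
    """Metadata of one record (one sample at one measurement time)."""

    sample_id: str
    species: str
    measurement_time: str
    nutrient_level: str | None = None
    habitat_group: str = field(default="")
    site: str = ""

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.measurement_time not in MEASUREMENT_TIMES:
            raise ValueError(
                f"unknown measurement time {self.measurement_time!r}; "
                f"expected one of {MEASUREMENT_TIMES}"
            )
        derived = _HABITAT_GROUPS[self.species]
        if self.habitat_group and self.habitat_group != derived:
            raise ValueError(
                f"habitat_group {self.habitat_group!r} contradicts the "
                f"species partition ({derived!r} for {self.species})"
            )
        object.__setattr__(self, "habitat_group", derived)
        if self.nutrient_level is None:
            object.__setattr__(self, "nutrient_level", NUTRIENT_LEVELS[self.species])

    @property
    def record_id(self) -> str:
        return f"{self.sample_id}_{self.measurement_time}"


class SpectralLibrary:
    """Reflectance matrix plus per-record metadata on a shared grid.

    Parameters
    ----------
    grid
        Common wavelength grid of every record.
    meta
        Sequence of :class:`SampleMeta`, one per row of ``reflectance``.
    reflectance
        Array of shape ``(n_records, len(grid))``, unitless reflectance
        factors (typically within [0, ~1.3]).
    """

    def __init__(
        self,
        grid: WavelengthGrid,
        meta: Sequence[SampleMeta],
        reflectance: np.ndarray,
    ) -> None:
        reflectance = np.asarray(reflectance, dtype=float)
        if reflectance.ndim != 2 or reflectance.shape != (len(meta), len(grid)):
            raise ValueError(
                f"reflectance shape {reflectance.shape} does not match "
                f"{len(meta)} records x {len(grid)} wavelengths"
            )
        ids = [m.record_id for m in meta]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")
        self.grid = grid
        self.meta = list(meta)
        self.reflectance = reflectance

    def __len__(self) -> int:
        return len(self.meta)

    def __iter__(self):
        return iter(zip(self.meta, self.reflectance))

    @property
    def record_ids(self) -> list[str]:
        return [m.record_id for m in self.meta]

    def meta_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame (one row per record)."""
        return pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in self.meta],
                "species": [m.species for m in self.meta],
                "nutrient_level": [m.nutrient_level for m in self.meta],
                "habitat_group": [m.habitat_group for m in self.meta],
                "site": [m.site for m in self.meta],
                "measurement_time": [m.measurement_time for m in self.meta],
            },
            index=self.record_ids,
        )

    def subset(
        self,
        *,
        time: str | None = None,
        species: str | Iterable[str] | None = None,
        habitat: str | Iterable[str] | None = None,
    ) -> "SpectralLibrary":
        """Records matching the given time / species / habitat-group filters."""
        if isinstance(species, str):
            species = (species,)
        if isinstance(habitat, str):
            habitat = (habitat,)
        keep = [
            i
            for i, m in enumerate(self.meta)
            if (time is None or m.measurement_time == time)
            and (species is None or m.species in set(species))
            and (habitat is None or m.habitat_group in set(habitat))
        ]
        return SpectralLibrary(
            self.grid, [self.meta[i] for i in keep], self.reflectance[keep]
        )

    def spectrum(self, record_id: str) -> np.ndarray:
        idx = self.record_ids.index(record_id)
        return self.reflectance[idx]


def _grid_from_wavelengths(w: np.ndarray) -> WavelengthGrid:
    steps = np.diff(w)
    if len(w) < 2 or np.any(steps <= 0):
        raise ValueError("wavelength column must be strictly increasing")
    if not np.allclose(steps, steps[0], atol=1e-9):
        raise ValueError("wavelength column is not a regular grid")
    return WavelengthGrid(float(w[0]), float(w[-1]), float(steps[0]))


_META_COLUMNS = ("sample_id", "species", "measurement_time")


def read_library(
    path: str | Path,
    metadata_path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> SpectralLibrary:
    """Read a spectra CSV + metadata CSV pair into a validated library.

    ``column_map`` renames metadata columns of a foreign layout onto the
    canonical names (``{"their_name": "sample_id", ...}``).  Every spectral
    column must join a metadata row on (sample_id, measurement_time); orphans
    on either side are an error.
    """
    spectra = pd.read_csv(path, comment="#")
    if "wavelength_nm" not in spectra.columns:
        raise ValueError("spectra file lacks a 'wavelength_nm' column")
    grid = _grid_from_wavelengths(spectra["wavelength_nm"].to_numpy(dtype=float))

    md = pd.read_csv(metadata_path, comment="#", dtype=str)
    if column_map:
        md = md.rename(columns=dict(column_map))
    missing = [c for c in _META_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"metadata file lacks columns {missing}")
    md_key = md["sample_id"] + "_" + md["measurement_time"]
    if md_key.duplicated().any():
        dupes = sorted(md_key[md_key.duplicated()].unique())
        raise ValueError(f"duplicated (sample_id, measurement_time) rows: {dupes}")
    md = md.set_index(md_key)

    record_cols = [c for c in spectra.columns if c != "wavelength_nm"]
    orphans = [c for c in record_cols if c not in md.index]
    if orphans:
        raise ValueError(f"spectral records without metadata: {sorted(orphans)}")

    def _opt(row, col):
        val = row.get(col)
        return None if val is None or pd.isna(val) else str(val)

    meta = []
    for rid in record_cols:
        row = md.loc[rid]
        meta.append(
            SampleMeta(
                sample_id=row["sample_id"],
                species=row["species"],
                measurement_time=row["measurement_time"],
                nutrient_level=_opt(row, "nutrient_level"),
                site=_opt(row, "site") or "",
            )
        )
    reflectance = spectra[record_cols].to_numpy(dtype=float).T
    return SpectralLibrary(grid, meta, reflectance)


def write_library(
    lib: SpectralLibrary,
    path: str | Path,
    metadata_path: str | Path,
    masses: pd.DataFrame | None = None,
) -> None:
    """Write the spectra + metadata CSV pair (lossless to ~1e-15 relative).

    If ``masses`` is given (indexed like the metadata, with columns
    ``fresh_mass_g``/``container_mass_g``/``dry_mass_g``) it is merged into
    the metadata file.
    """
    if len(lib) == 0:
        Path(path).write_text("wavelength_nm\n")
    else:
        wide = pd.DataFrame(
            lib.reflectance.T, columns=lib.record_ids, index=lib.grid.wavelengths
        )
        wide.index.name = "wavelength_nm"
        wide.to_csv(path, float_format="%.12g")

    md = lib.meta_frame()
    if masses is not None:
        md = md.join(masses)
    md.to_csv(metadata_path, index=False)


def resample_to_grid(
    wavelengths: np.ndarray, values: np.ndarray, grid: WavelengthGrid
) -> np.ndarray:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.asarray(values, dtype=float)
    if wavelengths.ndim != 1 or wavelengths.shape != values.shape:
        raise ValueError("wavelengths and values must be matching 1-D arrays")
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("input wavelengths must be strictly increasing")
    if wavelengths[0] > grid.start_nm or wavelengths[-1] < grid.end_nm:
        raise ValueError(
            "input range "
            f"[{wavelengths[0]}, {wavelengths[-1]}] nm does not cover the grid "
            f"[{grid.start_nm}, {grid.end_nm}] nm"
        )
    return np.interp(grid.wavelengths, wavelengths, values)
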