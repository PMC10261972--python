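"""Gravimetric moisture content and per-species drying summaries.

Moisture content of a moss sample at measurement time is defined on a
fresh-mass basis::

    Moist = (F_w - D_w) / F_w

where ``F_w`` is the sample mass at the time of the spectral measurement
(container subtracted) and ``D_w`` is its fully-dried mass, weighed once at
the end of the campaign.  The fraction lies in [0, 1); multiply by 100 for
percent.

Summaries report the *mean of per-sample moistures*, not the moisture of
mean masses; the two differ whenever masses vary across replicates (the
ratio is nonlinear), and agree only for low-variance species.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral_io import MEASUREMENT_TIMES, SpectralLibrary

__all__ = [
    "MassRecord",
    "MoistureValue",
    "moisture_fraction",
    "moisture_content",
    "species_moisture_table",
    "read_masses",
    "load_reference_masses",
    "reference_moisture_pct",
]


@dataclass(frozen=True)
class MassRecord:
    """Weighing of one sample at one measurement time (grams)."""

    sample_id: str
    measurement_time: str
    total_mass_g: float  # sample + container at measurement time
    container_mass_g: float
    dry_mass_g: float  # sample only, after complete drying

    def __post_init__(self) -> None:
        if self.total_mass_g <= self.container_mass_g:
            raise ValueError(
                f"{self.sample_id}/{self.measurement_time}: total mass "
                f"{self.total_mass_g} g does not exceed container "
                f"{self.container_mass_g} g"
            )
        if self.dry_mass_g < 0:
            raise ValueError("dry mass must be non-negative")

    @property
    def fresh_mass_g(self) -> float:
        """Sample mass at measurement time, container removed (F_w)."""
        return self.total_mass_g - self.container_mass_g


@dataclass(frozen=True)
class MoistureValue:
    moist_fraction: float

    @property
    def percent(self) -> float:
        return 100.0 * self.moist_fraction


def moisture_fraction(fresh_mass_g: float, dry_mass_g: float) -> float:
    """(F_w - D_w) / F_w as a fraction in [0, 1)."""
    if fresh_mass_g <= 0:
        raise ValueError(f"fresh mass must be positive, got {fresh_mass_g}")
    if dry_mass_g > fresh_mass_g:
        raise ValueError(
            f"dry mass {dry_mass_g} g exceeds fresh mass {fresh_mass_g} g "
            "(non-physical)"
        )
    return (fresh_mass_g - dry_mass_g) / fresh_mass_g


def moisture_content(m: MassRecord) -> MoistureValue:
    """Moisture content of one weighing."""
    return MoistureValue(moisture_fraction(m.fresh_mass_g, m.dry_mass_g))


def species_moisture_table(
    lib: SpectralLibrary, masses: list[MassRecord] | pd.DataFrame
) -> pd.DataFrame:
    """Species × time summary: mean moisture % and mean/sd sample mass.

    Every (sample, time) pair present in the library must have a mass
    record.  ``moist_pct`` is the mean of per-sample moisture percentages
    rounded to one decimal; ``mass_mean_g``/``mass_sd_g`` summarize the
    container-free mass F_w (sd with n−1, 0 for a single sample).
    """
    if isinstance(masses, pd.DataFrame):
        masses = masses_from_frame(masses)
    by_key = {(m.sample_id, m.measurement_time): m for m in masses}

    rows = []
    for meta in lib.meta:
        key = (meta.sample_id, meta.measurement_time)
        if key not in by_key:
            raise KeyError(f"no mass record for sample {key[0]} at {key[1]}")
        rec = by_key[key]
        rows.append(
            {
                "species": meta.species,
                "measurement_time": meta.measurement_time,
                "moist_pct": 100.0 * moisture_content(rec).moist_fraction,
                "fresh_mass_g": rec.fresh_mass_g,
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["species", "measurement_time"], sort=False)
        .agg(
            moist_pct=("moist_pct", "mean"),
            mass_mean_g=("fresh_mass_g", "mean"),
            mass_sd_g=("fresh_mass_g", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        )
        .reset_index()
    )
    out["moist_pct"] = out["moist_pct"].round(1)
    order = {t: i for i, t in enumerate(MEASUREMENT_TIMES)}
    out = out.sort_values(
        ["species", "measurement_time"],
        key=lambda s: s.map(order) if s.name == "measurement_time" else s,
        kind="stable",
    ).reset_index(drop=True)
    return out


def masses_from_frame(df: pd.DataFrame) -> list[MassRecord]:
    """Build mass records from a DataFrame with the canonical columns."""
    required = {
        "sample_id",
        "measurement_time",
        "total_mass_g",
        "container_mass_g",
        "dry_mass_g",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mass table lacks columns {sorted(missing)}")
    return [
        MassRecord(
            sample_id=str(r.sample_id),
            measurement_time=str(r.measurement_time),
            total_mass_g=float(r.total_mass_g),
            container_mass_g=float(r.container_mass_g),
            dry_mass_g=float(r.dry_mass_g),
        )
        for r in df.itertuples(index=False)
    ]


def read_masses(path: str | Path) -> list[MassRecord]:
    """Read a masses CSV (sample_id, measurement_time, total/container/dry)."""
    return masses_from_frame(pd.read_csv(path, comment="#"))


def load_reference_masses() -> pd.DataFrame:
    """Published species-level drying summary of the nine-species campaign.

    Columns: species, measurement_time ('0h'..'1week' plus 'dry'),
    moist_pct (as published), mass_mean_g, mass_sd_g.  Masses are
    container-free species means over 10 replicates.
    """
    with resources.files("sphagspec.data").joinpath(
        "species_drying_masses.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def reference_moisture_pct(species: str, time: str) -> float:
    """Moisture % recomputed from the published mean masses, one decimal.

    Applies the gravimetric formula to the species' mean mass at ``time``
    and its mean dry mass.  Because the formula is a nonlinear ratio, this
    matches the published per-sample-mean moisture only for species with
    low mass variance across replicates.
    """
    ref = load_reference_masses().set_index(["species", "measurement_time"])
    try:
        fresh = float(ref.loc[(species, time), "mass_mean_g"])
        dry = float(ref.loc[(species, "dry"), "mass_mean_g"])
    except KeyError:
        raise KeyError(f"no reference masses for {species!r} at {time!r}") from None
    return round(100.0 * moisture_fraction(fresh, dry), 1)
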