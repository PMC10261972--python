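"""End-to-end pipeline: preprocess → moisture → band stats → PCA/clustering → RI scan.

`run_pipeline` drives every analysis stage from one
:class:`PipelineConfig` (optionally loaded from YAML) and writes a bundle
of CSV tables plus a JSON run manifest.  Outputs are deterministic for a
fixed config: every CSV carries the config hash in a ``#`` header comment,
and two runs with the same config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import band_stats, moisture, multivariate, ratio_index
from .preprocess import SmoothingConfig, smooth_library
from .spectral_io import MEASUREMENT_TIMES, read_library
from .synthetic import SimulationConfig, generate_library

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on.

    Either ``library_csv``+``metadata_csv``+``masses_csv`` point at an
    existing library, or ``synthetic=True`` generates one with ``seed``.
    """

    out_dir: str = "results/pipeline"
    library_csv: str | None = None
    metadata_csv: str | None = None
    masses_csv: str | None = None
    synthetic: bool = False
    seed: int = 0
    times: tuple[str, ...] = ("0h", "1week")
    smooth_window_nm: float = 25.0
    smooth_polyorder: int = 2
    apply_smoothing: bool = True
    alpha: float = 0.05
    rep_window: tuple[float, float] = (680.0, 750.0)
    rep_method: str = "max_first_derivative"
    pca_n_pc: int = 3
    pca_scale_unit: bool = True
    cluster_k: int = 3
    cluster_linkage: str = "ward"
    ri_stride_nm: int = 1
    ri_range: tuple[float, float] | None = None
    r2_threshold: float = 0.7

    def __post_init__(self) -> None:
        unknown = set(self.times) - set(MEASUREMENT_TIMES)
        if unknown:
            raise ValueError(
                f"unknown measurement times {sorted(unknown)}; "
                f"expected a subset of {MEASUREMENT_TIMES}"
            )
        if not self.synthetic and not (self.library_csv and self.metadata_csv):
            raise ValueError(
                "either set synthetic=True or provide library_csv and metadata_csv"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("times", "rep_window", "ri_range"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the result bundle under ``cfg.out_dir``.

    Returns a mapping of artifact name → path.  On stage failure, partial
    outputs of this run are removed and :class:`PipelineError` is raised.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    artifacts: dict[str, Path] = {}
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        _write_csv(df, path, cfg_hash)
        written.append(path)
        artifacts[name] = path

    stage = "load"
    try:
        if cfg.synthetic:
            lib, masses_df = generate_library(SimulationConfig(seed=cfg.seed))
        else:
            lib = read_library(cfg.library_csv, cfg.metadata_csv)
            if not cfg.masses_csv:
                raise ValueError("masses_csv is required for a file-based run")
            masses_df = pd.read_csv(cfg.masses_csv, comment="#")
        masses = moisture.masses_from_frame(masses_df)
        log.info("loaded %d records", len(lib))

        if cfg.apply_smoothing:
            stage = "preprocess"
            lib = smooth_library(
                lib, SmoothingConfig(cfg.smooth_window_nm, cfg.smooth_polyorder)
            )

        stage = "moisture"
        moist_table = moisture.species_moisture_table(lib, masses)
        emit("moisture_summary", moist_table)
        moist_by_record = {
            (m.sample_id, m.measurement_time): 100.0
            * moisture.moisture_content(m).moist_fraction
            for m in masses
        }

        stage = "band_stats"
        region_rows, rep_frames = [], []
        species_present = sorted({m.species for m in lib.meta})
        if {"0h", "1week"} <= set(cfg.times):
            for sp in species_present:
                mask = band_stats.wilcoxon_bands(lib, sp, "0h", "1week", cfg.alpha)
                for start, end in mask.regions:
                    region_rows.append(
                        {"species": sp, "start_nm": start, "end_nm": end}
                    )
        emit(
            "significance_regions",
            pd.DataFrame(region_rows, columns=["species", "start_nm", "end_nm"]),
        )
        reps = band_stats.rep_library(lib, cfg.rep_window, cfg.rep_method)
        emit("rep", reps)
        for time in cfg.times:
            sub = lib.subset(time=time)
            curves = {
                "wavelength_nm": sub.grid.wavelengths,
                "r2_species": band_stats.variance_explained(sub, "species").r2,
            }
            if len({m.habitat_group for m in sub.meta} - {"excluded"}) == 2:
                curves["r2_habitat"] = band_stats.variance_explained(sub, "habitat").r2
            emit(f"variance_curves_{time}", pd.DataFrame(curves))

        stage = "multivariate"
        for time in cfg.times:
            pca = multivariate.run_pca(lib, time, scale_unit=cfg.pca_scale_unit)
            sub = lib.subset(time=time)
            n_show = min(cfg.pca_n_pc, pca.scores.shape[1])
            scores = pd.DataFrame(
                pca.scores[:, :n_show],
                columns=[f"pc{i + 1}" for i in range(n_show)],
            )
            scores.insert(0, "record_id", pca.record_ids)
            scores["species"] = [m.species for m in sub.meta]
            scores["habitat_group"] = [m.habitat_group for m in sub.meta]
            clust = multivariate.hierarchical_cluster(
                pca, n_pc=n_show, k=cfg.cluster_k, method=cfg.cluster_linkage
            )
            scores["cluster"] = clust.labels
            emit(f"pca_scores_{time}", scores)
            emit(
                f"pca_explained_{time}",
                pd.DataFrame(
                    {
                        "component": np.arange(1, len(pca.explained_fraction) + 1),
                        "explained_fraction": pca.explained_fraction,
                    }
                ),
            )
            emit(
                f"dendrogram_{time}",
                pd.DataFrame(
                    clust.linkage_matrix,
                    columns=["child_a", "child_b", "height", "n_members"],
                ),
            )
            emit(
                f"composition_{time}",
                multivariate.cluster_composition(clust, sub.meta),
            )

        stage = "ratio_index"
        best_rows, region_tables = [], []
        for time in cfg.times:
            sub_ids = {
                m.sample_id: moist_by_record[(m.sample_id, m.measurement_time)]
                for m in lib.subset(time=time).meta
            }
            scan = ratio_index.scan_all_pairs(
                lib,
                sub_ids,
                time=time,
                stride_nm=cfg.ri_stride_nm,
                wavelength_range=cfg.ri_range,
            )
            l1, l2, slope, icpt, r2, rmse = scan.best
            best_rows.append(
                {
                    "measurement_time": time,
                    "lambda1_nm": l1,
                    "lambda2_nm": l2,
                    "slope": slope,
                    "intercept": icpt,
                    "r2": r2,
                    "rmse": rmse,
                }
            )
            for reg in ratio_index.surface_summary(scan, cfg.r2_threshold):
                region_tables.append({"measurement_time": time, **asdict(reg)})
        emit("ri_best_pairs", pd.DataFrame(best_rows))
        emit(
            "ri_high_r2_regions",
            pd.DataFrame(
                region_tables,
                columns=[
                    "measurement_time",
                    "l1_start_nm",
                    "l1_end_nm",
                    "l2_start_nm",
                    "l2_end_nm",
                    "n_pairs",
                    "max_r2",
                ],
            ),
        )

        stage = "manifest"
        checksum = hashlib.sha256(
            np.ascontiguousarray(lib.reflectance).tobytes()
        ).hexdigest()[:16]
        manifest = {
            "config_hash": cfg_hash,
            "config": asdict(cfg),
            "library_checksum": checksum,
            "n_records": len(lib),
            "artifacts": sorted(p.name for p in written),
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        artifacts["manifest"] = manifest_path
    except Exception as exc:  # noqa: BLE001 - abort cleanly with stage context
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    return artifacts
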