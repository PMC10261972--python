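"""Spectral separability: PCA and hierarchical clustering.

A per-measurement-time PCA (centered, unit-variance-scaled by default, as
common multivariate packages in this field do) reduces the 2151-band
spectra to a few score columns; agglomerative clustering with Ward linkage
on Euclidean distances over the first three components then groups
samples, and the dendrogram is cut at a fixed number of clusters.  Cluster
composition against species / habitat labels quantifies how well spectral
proximity recovers the ecological partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .spectral_io import SampleMeta, SpectralLibrary

__all__ = [
    "PCAResult",
    "ClusterResult",
    "run_pca",
    "hierarchical_cluster",
    "cluster_composition",
]


@dataclass
class PCAResult:
    """Principal components of one library subset.

    ``components`` has one loading vector per row; ``scores`` is the
    record × component projection; ``explained_fraction`` spans the full
    rank (sums to 1).  Sign convention: the largest-magnitude loading of
    each component is positive, which makes score plots reproducible.
    """

    components: np.ndarray
    scores: np.ndarray
    explained_fraction: np.ndarray
    record_ids: list[str]
    centered: bool = True
    scaled: bool = True


def run_pca(
    lib: SpectralLibrary, time: str | None = None, scale_unit: bool = True
) -> PCAResult:
    """PCA of the spectra of one measurement time.

    Columns are centered and, with ``scale_unit`` (default, matching the
    usual multivariate-package behaviour), divided by their population
    standard deviation; constant bands are left at zero.  Eigenstructure
    comes from the SVD of the standardized matrix.
    """
    sub = lib.subset(time=time) if time is not None else lib
    x = sub.reflectance.astype(float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least two records")
    x = x - x.mean(axis=0)
    if scale_unit:
        sd = x.std(axis=0, ddof=0)
        nonzero = sd > 0
        x[:, nonzero] = x[:, nonzero] / sd[nonzero]

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # Fix signs so each component's largest-|loading| entry is positive.
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]

    total = float((s**2).sum())
    explained = (s**2) / total if total > 0 else np.zeros_like(s)
    return PCAResult(
        components=vt,
        scores=u * s,
        explained_fraction=explained,
        record_ids=sub.record_ids,
        centered=True,
        scaled=scale_unit,
    )


@dataclass
class ClusterResult:
    """Agglomerative clustering of PCA scores.

    ``linkage_matrix`` is the scipy merge table (heights non-decreasing for
    Ward on Euclidean distances); ``labels`` are 1..k cluster ids from
    cutting the tree at ``k`` clusters.
    """

    linkage_matrix: np.ndarray
    labels: np.ndarray
    k: int
    n_pc: int
    method: str
    record_ids: list[str]


def hierarchical_cluster(
    p: PCAResult, n_pc: int = 3, k: int = 3, method: str = "ward"
) -> ClusterResult:
    """Cluster records on their first ``n_pc`` score columns, cut at ``k``."""
    n = p.scores.shape[0]
    if n_pc > p.scores.shape[1]:
        raise ValueError(f"only {p.scores.shape[1]} components available")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    z = linkage(p.scores[:, :n_pc], method=method, metric="euclidean")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterResult(z, labels, k=k, n_pc=n_pc, method=method,
                         record_ids=list(p.record_ids))


def cluster_composition(
    c: ClusterResult, meta: list[SampleMeta], by: str = "habitat_group"
) -> pd.DataFrame:
    """Contingency counts and majority purity of each cluster.

    ``by`` is the SampleMeta field to tabulate (``habitat_group`` or
    ``species``).  Purity is the fraction of the cluster's records carrying
    its most frequent label.
    """
    if len(meta) != len(c.labels):
        raise ValueError("metadata and cluster labels have different lengths")
    labels = pd.Series(c.labels, name="cluster")
    cats = pd.Series([getattr(m, by) for m in meta], name=by)
    counts = pd.crosstab(labels, cats)
    purity = counts.max(axis=1) / counts.sum(axis=1)
    out = counts.copy()
    out["size"] = counts.sum(axis=1)
    out["purity"] = purity
    return out.reset_index()
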