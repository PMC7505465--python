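"""Single-sample pathway enrichment of cluster centroids.

Each cluster's centroid is treated as one pseudo-bulk sample and scored
against every gene set with a gene-set variation analysis (GSVA-style)
statistic: a kernel-smoothed cumulative density estimate per gene across
clusters, converted to centred within-cluster ranks, followed by a weighted
Kolmogorov-Smirnov-like random walk down each cluster's ranked gene list.
The resulting pathway x cluster matrix ("pathway enrichment profile" of each
cluster) is the coordinate system for all downstream trajectory steps.

Conventions follow the common defaults of the reference GSVA approach:
Gaussian kernel with bandwidth = per-gene standard deviation / 4, weight
exponent tau = 1, and the magnitude-difference enrichment statistic (sum of
the largest positive and largest negative walk deviations).  The centred
rank statistic is the symmetric ``|rank - (G+1)/2|`` so that reversing a
cluster's ranking exactly negates the score on tie-free data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from .io import PathwayCollection

_GENE_BLOCK = 4096  # rows per kernel-CDF block, bounds the G x K x K temporary


@dataclass
class EnrichmentMatrix:
    """Pathway x cluster enrichment scores."""

    scores: pd.DataFrame  # index = pathway names, columns = cluster ids

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValueError("enrichment scores contain non-finite values")
        if self.scores.index.has_duplicates or self.scores.columns.has_duplicates:
            raise ValueError("duplicate pathway or cluster names")

    @property
    def pathway_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.scores.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnrichmentMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class AnnotationResult:
    """Cell-type labels per cluster from marker-set enrichment."""

    labels: dict[str, str]  # cluster id -> label ("A/B" on ties, "unresolved")
    score_table: pd.DataFrame  # cell types x clusters


def kernel_cdf_statistic(X: np.ndarray) -> np.ndarray:
    """Gaussian-kernel cumulative density estimate of each entry.

    For gene g in sample j the statistic is the mean over samples k of
    ``Phi((x_gj - x_gk) / h_g)`` with bandwidth ``h_g = sd_g / 4``.  A gene
    constant across samples (sd 0) gets 0.5 everywhere: all its values are
    tied, and the downstream average-rank step treats them as such.
    """
    X = np.asarray(X, dtype=float)
    n_genes, k = X.shape
    h = X.std(axis=1, ddof=1) / 4.0
    out = np.empty_like(X)
    for start in range(0, n_genes, _GENE_BLOCK):
        sl = slice(start, start + _GENE_BLOCK)
        hb = h[sl]
        safe = np.where(hb > 0, hb, 1.0)
        diff = (X[sl, :, None] - X[sl, None, :]) / safe[:, None, None]
        out[sl] = ndtr(diff).mean(axis=2)
        out[sl][hb == 0] = 0.5
    return out


def _centred_ranks(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster gene ranks of the kernel statistic.

    Returns ``(weight, order)``: ``weight[g, j] = |rank_gj - (G+1)/2|`` with
    average ranks on ties, and ``order[:, j]`` the walk order for cluster j
    (decreasing statistic, ties broken stably by gene index).
    """
    n_genes, k = z.shape
    weight = np.empty_like(z)
    order = np.empty_like(z, dtype=np.intp)
    centre = (n_genes + 1) / 2.0
    idx = np.arange(n_genes)
    for j in range(k):
        ranks = rankdata(z[:, j], method="average")
        weight[:, j] = np.abs(ranks - centre)
        order[:, j] = np.lexsort((idx, -z[:, j]))
    return weight, order


def _walk_scores(
    weight: np.ndarray,
    order: np.ndarray,
    member_mask: np.ndarray,
    tau: float,
    convention: str,
) -> np.ndarray:
    """KS-like random walk of one gene set down every cluster's ranked list."""
    n_genes, k = weight.shape
    n_in = int(member_mask.sum())
    es = np.empty(k)
    for j in range(k):
        ordered = order[:, j]
        in_set = member_mask[ordered]
        w = np.where(in_set, weight[ordered, j] ** tau, 0.0)
        w_total = w.sum()
        pos = np.cumsum(w) / w_total if w_total > 0 else np.zeros(n_genes)
        neg = np.cumsum(~in_set) / (n_genes - n_in)
        nu = pos - neg
        if convention == "magnitude_difference":
            es[j] = max(nu.max(), 0.0) + min(nu.min(), 0.0)
        elif convention == "max_deviation":
            es[j] = nu[np.argmax(np.abs(nu))]
        else:
            raise ValueError(f"unknown ES convention {convention!r}")
    return es


def enrich(
    centroids: pd.DataFrame,
    pathways: PathwayCollection,
    tau: float = 1.0,
    convention: str = "magnitude_difference",
    min_genes: int = 2,
) -> EnrichmentMatrix:
    """Score every pathway in every cluster.

    Parameters
    ----------
    centroids
        Genes x clusters matrix of centroid expression (one pseudo-bulk
        sample per cluster).
    pathways
        Gene sets; sets with fewer than ``min_genes`` members present in the
        centroid gene index are dropped with a warning.
    tau
        Weight exponent on the centred rank statistic in the random walk.
    convention
        ``"magnitude_difference"`` (sum of the extreme positive and negative
        deviations, the default) or ``"max_deviation"`` (the single deviation
        of largest magnitude, keeping its sign).
    """
    if centroids.shape[1] < 2:
        raise ValueError("enrichment needs >= 2 clusters (density across samples)")
    if centroids.shape[1] < 5:
        warnings.warn(
            f"only {centroids.shape[1]} clusters: kernel density estimates "
            "across so few samples are coarse",
            stacklevel=2,
        )
    if len(pathways) == 0:
        raise ValueError("empty pathway collection")
    gene_pos = {g: i for i, g in enumerate(centroids.index)}
    z = kernel_cdf_statistic(centroids.to_numpy())
    weight, order = _centred_ranks(z)
    rows: dict[str, np.ndarray] = {}
    n_genes = centroids.shape[0]
    for name, genes in pathways:
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if len(idx) < min_genes:
            warnings.warn(f"pathway {name!r}: {len(idx)} genes in data, dropped", stacklevel=2)
            continue
        if len(idx) == n_genes:
            warnings.warn(f"pathway {name!r} covers every gene, dropped", stacklevel=2)
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        rows[name] = _walk_scores(weight, order, mask, tau, convention)
    if not rows:
        raise ValueError("no pathway had enough genes in the data")
    return EnrichmentMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=centroids.columns)
    )


def annotate_clusters(
    centroids: pd.DataFrame,
    marker_sets: PathwayCollection,
    tie_tol: float = 1e-12,
) -> AnnotationResult:
    """Label clusters by their best-scoring marker gene set.

    Marker sets need only two genes in the data (size bounds for curated
    marker lists are relaxed relative to pathway databases).  Ties within
    ``tie_tol`` of the column maximum are joined with "/"; a cluster whose
    scores are all equal is labelled "unresolved".
    """
    em = enrich(centroids, marker_sets, min_genes=2)
    labels: dict[str, str] = {}
    for cluster in em.cluster_ids:
        col = em.scores[cluster]
        if len(col) > 1 and float(col.max() - col.min()) <= tie_tol:
            labels[cluster] = "unresolved"
            continue
        winners = [n for n in em.pathway_names if col[n] >= col.max() - tie_tol]
        labels[cluster] = "/".join(winners)
    return AnnotationResult(labels=labels, score_table=em.scores)
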