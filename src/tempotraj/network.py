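"""Mutual-information cluster network with data-processing-inequality pruning.

Clusters are connected by the mutual information between their pathway
enrichment profiles, the dependence measure the ARACNE family of network
methods uses.  The estimator is rank-based and therefore invariant to any
strictly monotone transform of either profile: both vectors are rank
transformed, ranks are cut into ``B = floor(sqrt(m))`` equal-frequency bins,
and MI is the plug-in (maximum-likelihood) estimate from the joint bin
table, in nats.

Indirect connections are removed with the data-processing inequality (DPI):
in every triangle of the complete MI graph, the lowest-MI edge is presumed
indirect and marked; all marked edges are removed simultaneously, so the
result does not depend on triangle enumeration order.  No absolute MI
threshold is applied — every edge that survives DPI is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class MINetwork:
    """Undirected MI-weighted cluster graph after DPI pruning."""

    nodes: list[str]
    edges: dict[frozenset, float]            # surviving edges
    removed_by_dpi: dict[frozenset, float] = field(default_factory=dict)

    def weight(self, a: str, b: str) -> float:
        return self.edges[frozenset((a, b))]

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        for pair, w in {**self.edges, **self.removed_by_dpi}.items():
            a, b = sorted(pair)
            rows.append((a, b, w, int(pair in self.removed_by_dpi)))
        rows.sort()
        return pd.DataFrame(rows, columns=["source", "target", "mi", "removed_by_dpi"])

    def write_tsv(self, path: str | Path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False)


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign rank-transformed values to ``n_bins`` equal-frequency bins."""
    m = len(x)
    ranks = rankdata(x, method="average")
    return np.minimum(((ranks - 1) * n_bins / m).astype(int), n_bins - 1)


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int | None = None) -> float:
    """Rank-based plug-in mutual information between two profiles, in nats.

    Parameters
    ----------
    x, y
        Profile vectors of equal length ``m`` (here: enrichment values of
        two clusters over the selected pathways).
    bins
        Number of equal-frequency bins; default ``max(2, floor(sqrt(m)))``.

    A constant vector collapses to a single bin, giving MI exactly 0; this
    is reported with a warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D vectors of equal length")
    m = len(x)
    if m < 8:
        raise ValueError(f"profile length {m} < 8: too few features for binning")
    if m < 25:
        warnings.warn(f"profile length {m} < 25: MI estimates are coarse", stacklevel=2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant profile: MI defined as 0", stacklevel=2)
        return 0.0
    b = bins if bins is not None else max(2, int(np.sqrt(m)))
    bx = _equal_frequency_bins(x, b)
    by = _equal_frequency_bins(y, b)
    joint = np.zeros((b, b))
    np.add.at(joint, (bx, by), 1.0)
    joint /= m
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))
    return max(mi, 0.0)


def build_network(
    profiles: pd.DataFrame,
    dpi_tolerance: float = 0.0,
    bins: int | None = None,
) -> MINetwork:
    """Complete pairwise-MI graph on clusters, pruned by the DPI.

    Parameters
    ----------
    profiles
        Features x clusters matrix (rows: selected pathway enrichment
        values, or genes in the no-enrichment ablation).
    dpi_tolerance
        An edge is marked for removal in a triangle when its MI is at most
        ``min(other two edges) - dpi_tolerance``.  At the default 0 this
        marks every edge attaining the triangle minimum, so exact ties are
        removed together (conservative and deterministic); larger values
        prune less.
    """
    clusters = list(profiles.columns)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters to build a network")
    if len(clusters) == 2:
        warnings.warn("2 clusters: single-edge trajectory is trivial", stacklevel=2)
    mi: dict[frozenset, float] = {}
    for a, b in combinations(clusters, 2):
        mi[frozenset((a, b))] = mutual_information(
            profiles[a].to_numpy(), profiles[b].to_numpy(), bins=bins
        )
    marked: set[frozenset] = set()
    for a, b, c in combinations(clusters, 3):
        e = [frozenset((a, b)), frozenset((b, c)), frozenset((a, c))]
        w = [mi[x] for x in e]
        for i, edge in enumerate(e):
            others = min(w[(i + 1) % 3], w[(i + 2) % 3])
            if w[i] <= others - dpi_tolerance:
                marked.add(edge)
    edges = {pair: w for pair, w in mi.items() if pair not in marked}
    removed = {pair: mi[pair] for pair in marked}
    return MINetwork(nodes=clusters, edges=edges, removed_by_dpi=removed)
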