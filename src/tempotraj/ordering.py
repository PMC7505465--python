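"""Temporal scoring and edge orientation of the cluster network.

Each time point gets a sequential ordinal value 1..N in collection order,
and a cluster whose cells come in fractions p_1..p_N from those time points
receives the temporal score

    T_k = sum_i p_i * i,

the composition-weighted mean ordinal time (1 for a cluster purely from the
first time point, N for one purely from the last).  Edges of the MI network
are directed from the lower-scoring to the higher-scoring endpoint, under
the assumption that differentiation proceeds forward in time.  Edges whose
endpoint scores are nearly equal — relative difference below the similarity
threshold, i.e. the scores agree to better than 99% at the default 0.01 —
are left undirected ("dashed"): they may represent small state transitions
where the unidirectional assumption is not trustworthy.  Dashed edges count
as bidirectional in every downstream comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ClusterProfile
from .network import MINetwork


@dataclass
class TrajectoryGraph:
    """Oriented cluster-level trajectory."""

    nodes: list[str]
    temporal_scores: dict[str, float]
    directed_edges: list[tuple[str, str]]          # (early, late)
    undirected_edges: list[frozenset]              # "dashed"
    annotations: dict[str, str] = field(default_factory=dict)
    similarity_threshold: float = 0.01
    similarity_mode: str = "relative"

    def roots(self) -> list[str]:
        """Nodes with no incoming directed edge."""
        targets = {v for _, v in self.directed_edges}
        return [n for n in self.nodes if n not in targets]

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (u, v, 1, self.temporal_scores[u], self.temporal_scores[v])
            for u, v in self.directed_edges
        ]
        for pair in self.undirected_edges:
            u, v = sorted(pair)
            rows.append((u, v, 0, self.temporal_scores[u], self.temporal_scores[v]))
        return pd.DataFrame(
            rows, columns=["source", "target", "directed", "T_source", "T_target"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False)

    def to_dot(self) -> str:
        lines = ["digraph trajectory {", "  rankdir=TB;"]
        for n in self.nodes:
            label = self.annotations.get(n, n)
            lines.append(
                f'  "{n}" [label="{label}\\nT={self.temporal_scores[n]:.2f}"];'
            )
        for u, v in self.directed_edges:
            lines.append(f'  "{u}" -> "{v}";')
        for pair in self.undirected_edges:
            u, v = sorted(pair)
            lines.append(f'  "{u}" -> "{v}" [dir=none, style=dashed];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def write_dot(self, path: str | Path) -> None:
        Path(path).write_text(self.to_dot())


def temporal_score(composition: np.ndarray | Sequence[float]) -> float:
    """T = sum_i p_i * i for a composition vector over time points 1..N."""
    p = np.asarray(composition, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"composition sums to {p.sum()}, expected 1")
    return float(np.dot(p, np.arange(1, len(p) + 1)))


def scores_from_profiles(profiles: Sequence[ClusterProfile]) -> dict[str, float]:
    return {p.cluster_id: temporal_score(p.composition) for p in profiles}


def orient(
    net: MINetwork,
    scores: Mapping[str, float],
    similarity_threshold: float = 0.01,
    similarity_mode: str = "relative",
    annotations: Mapping[str, str] | None = None,
) -> TrajectoryGraph:
    """Orient MI edges early -> late; leave near-tied edges dashed.

    Parameters
    ----------
    net
        DPI-pruned mutual-information network.
    scores
        Temporal score per cluster.
    similarity_threshold, similarity_mode
        In ``"relative"`` mode (default) an edge (a, b) stays undirected
        when ``|T_a - T_b| / max(T_a, T_b) < threshold``; in ``"absolute"``
        mode when ``|T_a - T_b| < threshold``.  Exactly equal scores are
        always dashed.
    """
    missing = [n for n in net.nodes if n not in scores]
    if missing:
        raise ValueError(f"no temporal score for nodes {missing}")
    directed: list[tuple[str, str]] = []
    dashed: list[frozenset] = []
    for pair in sorted(net.edges, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        ta, tb = scores[a], scores[b]
        if similarity_mode == "relative":
            similar = abs(ta - tb) / max(ta, tb) < similarity_threshold
        elif similarity_mode == "absolute":
            similar = abs(ta - tb) < similarity_threshold
        else:
            raise ValueError(f"unknown similarity mode {similarity_mode!r}")
        if similar:
            dashed.append(pair)
        elif ta < tb:
            directed.append((a, b))
        else:
            directed.append((b, a))
    return TrajectoryGraph(
        nodes=list(net.nodes),
        temporal_scores={n: float(scores[n]) for n in net.nodes},
        directed_edges=directed,
        undirected_edges=dashed,
        annotations=dict(annotations or {}),
        similarity_threshold=similarity_threshold,
        similarity_mode=similarity_mode,
    )


def layered_layout(traj: TrajectoryGraph) -> dict[str, tuple[float, float]]:
    """Sugiyama-style layer assignment: layers ordered by temporal score."""
    order = sorted(traj.nodes, key=lambda n: (traj.temporal_scores[n], n))
    layers: list[list[str]] = []
    last_score: float | None = None
    for n in order:
        s = traj.temporal_scores[n]
        if last_score is None or not np.isclose(s, last_score):
            layers.append([])
        layers[-1].append(n)
        last_score = s
    pos: dict[str, tuple[float, float]] = {}
    for depth, layer in enumerate(layers):
        for i, n in enumerate(layer):
            pos[n] = (i - (len(layer) - 1) / 2.0, -float(depth))
    return pos


def draw(traj: TrajectoryGraph, out: str | Path) -> None:
    """Render the trajectory as a layered drawing (PNG/SVG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = layered_layout(traj)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for u, v in traj.directed_edges:
        (x0, y0), (x1, y1) = pos[u], pos[v]
        ax.annotate(
            "", xy=(x1, y1), xytext=(x0, y0),
            arrowprops=dict(arrowstyle="-|>", color="0.3", shrinkA=14, shrinkB=14),
        )
    for pair in traj.undirected_edges:
        u, v = sorted(pair)
        (x0, y0), (x1, y1) = pos[u], pos[v]
        ax.plot([x0, x1], [y0, y1], ls="--", color="0.5", zorder=0)
    for n, (x, y) in pos.items():
        ax.scatter([x], [y], s=600, color="tab:blue", zorder=2)
        ax.annotate(traj.annotations.get(n, n), (x, y), ha="center", va="center",
                    fontsize=7, color="white", zorder=3)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
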