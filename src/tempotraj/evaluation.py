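"""Scoring inferred trajectories against gold-standard lineages.

Gold standards are directed graphs at the cell-type level (nodes are cell
types, edges are develops-from relationships), while predictions come at
the cluster level with cell-type annotations; before scoring, clusters
sharing a label are collapsed to one node and parallel edges merge.

Two scores are provided.  The *mismatch score* is an unweighted graph-edit
style count on the undirected, label-collapsed graphs: the number of cell
types present in exactly one graph plus the number of unordered label pairs
adjacent in exactly one graph.  The *accuracy (F1) score* works on directed
edges: a predicted edge is a true positive only when both endpoints and the
direction match the gold standard; undirected ("dashed") predicted edges
expand to both directions, and bidirectional gold edges are satisfied by
either direction.

For methods that output undirected trajectories, edges can first be
oriented outward from marker-identified root cell types; edges that a
breadth-first search from the roots cannot order (equal depth, or in a
component with no root) are left bidirectional.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

DIRECTIONS = ("forward", "bidirectional", "undirected")


@dataclass
class LabeledGraph:
    """Trajectory graph over cell-type labels.

    ``nodes`` is a label multiset (two clusters may share a type); edges are
    ``(source, target, direction)`` with direction ``"forward"``,
    ``"bidirectional"`` or ``"undirected"``.  Undirected and bidirectional
    edges are equivalent for scoring; both expand to the two directions.
    """

    nodes: list[str]
    edges: list[tuple[str, str, str]] = field(default_factory=list)
    root_markers: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.nodes)
        for u, v, d in self.edges:
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            if u not in labels or v not in labels:
                raise ValueError(f"edge ({u!r}, {v!r}) endpoint missing from nodes")
            if d not in DIRECTIONS:
                raise ValueError(f"unknown edge direction {d!r}")

    # -- label-collapsed views ------------------------------------------
    def undirected_pairs(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v, _ in self.edges}

    def directed_set(self) -> set[tuple[str, str]]:
        """Directed edges after expanding bidirectional/undirected ones."""
        out: set[tuple[str, str]] = set()
        for u, v, d in self.edges:
            out.add((u, v))
            if d in ("bidirectional", "undirected"):
                out.add((v, u))
        return out

    @classmethod
    def from_tsv(cls, edges_path: str | Path, nodes: list[str] | None = None) -> "LabeledGraph":
        """Read an edge list TSV: source_label, target_label, direction."""
        df = pd.read_csv(edges_path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{edges_path}: need >= 2 columns")
        edges = []
        for row in df.itertuples(index=False):
            d = row[2] if len(row) > 2 and isinstance(row[2], str) else "forward"
            edges.append((str(row[0]), str(row[1]), d))
        if nodes is None:
            nodes = list(dict.fromkeys([u for u, _, _ in edges] + [v for _, v, _ in edges]))
        return cls(nodes=nodes, edges=edges)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.edges, columns=["source", "target", "direction"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class EvaluationResult:
    mismatch: int
    precision: float
    recall: float
    f1: float
    tp: list[tuple[str, str]]
    fp: list[tuple[str, str]]
    fn: list[tuple[str, str]]


def mismatch_score(pred: LabeledGraph, gold: LabeledGraph) -> int:
    """Undirected graph-edit mismatch: label differences + adjacency differences.

    Node difference is the size of the symmetric difference of the label
    multisets; adjacency difference counts each unordered label pair that is
    adjacent in exactly one of the label-collapsed undirected graphs once.
    """
    if not gold.nodes:
        raise ValueError("gold-standard graph is empty")
    pc, gc = Counter(pred.nodes), Counter(gold.nodes)
    node_diff = sum(((pc - gc) + (gc - pc)).values())
    adj_diff = len(pred.undirected_pairs() ^ gold.undirected_pairs())
    return node_diff + adj_diff


def f1_score(pred: LabeledGraph, gold: LabeledGraph) -> EvaluationResult:
    """Directed-edge precision/recall/F1 against the gold standard.

    Predicted bidirectional (or dashed) edges contribute both directions,
    each scored separately; a bidirectional gold edge is satisfied by either
    direction and counts one false negative only if neither is predicted.
    """
    pred_dir = pred.directed_set()
    gold_dir = gold.directed_set()
    tp = sorted(pred_dir & gold_dir)
    fp = sorted(pred_dir - gold_dir)
    # gold false negatives at the level of gold edges, not expanded arcs
    fn: list[tuple[str, str]] = []
    for u, v, d in gold.edges:
        if d in ("bidirectional", "undirected"):
            if (u, v) not in pred_dir and (v, u) not in pred_dir:
                fn.append((u, v))
        elif (u, v) not in pred_dir:
            fn.append((u, v))
    n_tp, n_fp, n_fn = len(tp), len(fp), len(fn)
    precision = n_tp / (n_tp + n_fp) if n_tp + n_fp else 0.0
    recall = n_tp / (n_tp + n_fn) if n_tp + n_fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvaluationResult(
        mismatch=mismatch_score(pred, gold),
        precision=precision,
        recall=recall,
        f1=f1,
        tp=tp,
        fp=fp,
        fn=sorted(fn),
    )


def orient_from_root(undirected: LabeledGraph, root_labels: set[str]) -> LabeledGraph:
    """Direct edges outward from marker-identified root cell types.

    Multi-source BFS from all roots over the label-collapsed undirected
    graph; each edge points from the shallower to the deeper endpoint.
    Edges between equal-depth nodes, and all edges in components containing
    no root, stay bidirectional.  Idempotent when reapplied with the same
    roots.
    """
    labels = set(undirected.nodes)
    roots = sorted(root_labels & labels)
    if not roots:
        raise ValueError(
            f"no node matches root labels {sorted(root_labels)}; nodes are {sorted(labels)}"
        )
    adj: dict[str, set[str]] = {n: set() for n in labels}
    for pair in undirected.undirected_pairs():
        u, v = sorted(pair)
        adj[u].add(v)
        adj[v].add(u)
    depth: dict[str, int] = {r: 0 for r in roots}
    queue = deque(roots)
    while queue:
        u = queue.popleft()
        for v in sorted(adj[u]):
            if v not in depth:
                depth[v] = depth[u] + 1
                queue.append(v)
    edges: list[tuple[str, str, str]] = []
    for pair in sorted(undirected.undirected_pairs(), key=lambda p: tuple(sorted(p))):
        u, v = sorted(pair)
        du, dv = depth.get(u), depth.get(v)
        if du is None or dv is None or du == dv:
            edges.append((u, v, "bidirectional"))
        elif du < dv:
            edges.append((u, v, "forward"))
        else:
            edges.append((v, u, "forward"))
    return LabeledGraph(nodes=list(undirected.nodes), edges=edges,
                        root_markers=dict(undirected.root_markers))


def trajectory_to_labeled_graph(traj, annotations: dict[str, str] | None = None) -> LabeledGraph:
    """Collapse a TrajectoryGraph to cell-type labels for evaluation.

    ``annotations`` maps cluster id to cell-type label (default: cluster id
    itself).  Edges between clusters that collapse to the same label are
    dropped (they become self-loops); duplicate directed edges merge, and a
    pair predicted in both directions becomes a single bidirectional edge.
    """
    ann = annotations or {}
    label = lambda n: ann.get(n, n)
    nodes = list(dict.fromkeys(label(n) for n in traj.nodes))
    directed: set[tuple[str, str]] = set()
    undirected: set[frozenset] = set()
    for u, v in traj.directed_edges:
        if label(u) != label(v):
            directed.add((label(u), label(v)))
    for pair in traj.undirected_edges:
        u, v = sorted(pair)
        if label(u) != label(v):
            undirected.add(frozenset((label(u), label(v))))
    edges: list[tuple[str, str, str]] = []
    seen: set[frozenset] = set()
    for u, v in sorted(directed):
        pair = frozenset((u, v))
        if pair in seen:
            continue
        if (v, u) in directed or pair in undirected:
            edges.append((min(u, v), max(u, v), "bidirectional"))
        else:
            edges.append((u, v, "forward"))
        seen.add(pair)
    for pair in sorted(undirected, key=lambda p: tuple(sorted(p))):
        if pair not in seen:
            u, v = sorted(pair)
            edges.append((u, v, "undirected"))
            seen.add(pair)
    return LabeledGraph(nodes=nodes, edges=edges)
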