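"""Synthetic time-series scRNA-seq data with a planted cluster lineage.

The generator emulates the transcriptional organisation of tissue
development that the pipeline assumes in real data: K cell clusters on a
known lineage tree, sampled over N time points with cluster compositions
shifting from early to late along the tree, and gene "programs" (synthetic
pathways) organised in modules whose activity varies smoothly along the
lineage.

For the default six-cluster chain-plus-branch lineage (root C0 -> C1 hub,
C1 -> C2 -> C3 and C1 -> C4 -> C5 branches) the modules follow the classic
developmental archetypes:

* a stemness module, maximal at the root and declining with depth;
* a progenitor module, transient with its peak at the hub cluster;
* a differentiation ramp per branch, rising monotonically to the branch
  terminus, with partial "lineage priming" already visible at the hub.

The two branch ramps are deliberately asymmetric (different priming levels,
ramp speeds and module sizes): real branches are never mirror images, and a
perfectly symmetric design creates an artificial one-to-one correspondence
between the two branches' profiles that no real tissue shows.  Each
individual program perturbs its module pattern with a random monotone power
warp (programs saturate at different rates), a log-normal amplitude and
small additive jitter, so the pathway collection is diverse rather than
600 copies of four vectors.  For non-default lineages, modules are
constructed automatically with one module family anchored at the root, at
each child of the root and at each leaf, with per-program random decay of
activity in tree distance from the anchor; this general construction is a
reasonable emulation but has not been curated the way the default table
has.

Expression is Gaussian around cluster means on a log-like scale: gene g of
program m in cluster k has mean ``mu0 + delta * a[m, k]`` (background genes
stay at ``mu0``) and each cell adds i.i.d. noise with standard deviation
``sigma``.  Count-level artefacts of real scRNA-seq (dropout, doublets,
batch effects) are deliberately not modelled; the analytic means keep every
stage oracle-checkable.

Everything is deterministic under the seed, and the planted lineage is
emitted as a gold-standard graph alongside GMT-compatible program sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import LabeledGraph
from .io import ClusterTable, ExpressionMatrix, PathwayCollection

DEFAULT_LINEAGE = [("C0", "C1"), ("C1", "C2"), ("C2", "C3"), ("C1", "C4"), ("C4", "C5")]

# module -> (activity pattern over C0..C5, number of programs)
DEFAULT_MODULES: dict[str, tuple[list[float], int]] = {
    "STEM":    ([1.0, 0.60, 0.22, 0.08, 0.30, 0.12], 170),
    "PROG":    ([0.30, 1.0, 0.55, 0.20, 0.42, 0.18], 150),
    "BRANCHA": ([0.0, 0.22, 0.72, 1.0, 0.04, 0.01], 150),
    "BRANCHB": ([0.06, 0.42, 0.10, 0.03, 0.68, 1.0], 130),
}


@dataclass
class SimulationSpec:
    """Parameters of the planted-lineage simulation.

    Defaults describe a 6-cluster chain-plus-branch tree over 4 time points
    with program effect size delta = 2 against noise sigma = 0.5 and 80
    cells per cluster.  The pathway space mimics a curated database after
    size filtering: 600 informative programs in four developmental modules
    plus 20 decoy sets drawn from background genes.
    """

    lineage: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_LINEAGE))
    n_timepoints: int = 4
    cells_per_cluster: int = 80
    modules: dict[str, tuple[list[float], int]] | None = None  # None -> default table
    genes_per_program: int = 8
    background_genes: int = 300
    n_decoy_sets: int = 20
    decoy_set_size: int = 30
    delta: float = 2.0          # log-expression shift per unit program activity
    sigma: float = 0.5          # per-cell Gaussian noise sd
    mu0: float = 1.0            # baseline mean expression
    pattern_jitter: float = 0.15    # additive per-program pattern noise
    amplitude_sd: float = 0.3       # sd of log-normal program amplitudes
    warp_range: tuple[float, float] = (0.7, 1.4)  # monotone power-warp exponents
    composition_width: float = 0.6  # sd of the time-composition kernel (time units)
    seed: int = 1

    def clusters(self) -> list[str]:
        out: list[str] = []
        for u, v in self.lineage:
            for n in (u, v):
                if n not in out:
                    out.append(n)
        return out

    def parents(self) -> dict[str, str]:
        par: dict[str, str] = {}
        for u, v in self.lineage:
            if v in par:
                raise ValueError(f"cluster {v!r} has two parents; lineage must be a tree")
            par[v] = u
        return par

    def depths(self) -> dict[str, int]:
        par = self.parents()
        roots = [n for n in self.clusters() if n not in par]
        if not roots:
            raise ValueError("lineage has no root (cycle?)")
        depth = dict.fromkeys(roots, 0)
        changed = True
        while changed:
            changed = False
            for v, u in par.items():
                if u in depth and v not in depth:
                    depth[v] = depth[u] + 1
                    changed = True
        if set(depth) != set(self.clusters()):
            raise ValueError("lineage is not a rooted tree reachable from its roots")
        return depth

    def module_table(self) -> dict[str, tuple[list[float], int]]:
        if self.modules is not None:
            return self.modules
        if self.lineage == DEFAULT_LINEAGE:
            return DEFAULT_MODULES
        return _anchored_modules(self)


def _tree_distances(spec: SimulationSpec) -> dict[str, dict[str, int]]:
    clusters = spec.clusters()
    adj: dict[str, set[str]] = {c: set() for c in clusters}
    for u, v in spec.lineage:
        adj[u].add(v)
        adj[v].add(u)
    out: dict[str, dict[str, int]] = {}
    for src in clusters:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in sorted(adj[u]):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        out[src] = dist
    return out


def _anchored_modules(spec: SimulationSpec) -> dict[str, tuple[list[float], int]]:
    """Fallback module table for non-default lineages.

    One module family per anchor (the root, each child of the root, each
    leaf) with activity ``rho ** distance(anchor, cluster)``; per-family
    decay rates mirror the default table's stem/progenitor/terminal roles.
    """
    clusters = spec.clusters()
    parents = spec.parents()
    dist = _tree_distances(spec)
    root = [c for c in clusters if c not in parents][0]
    hubs = [v for u, v in spec.lineage if u == root]
    has_child = {u for u, _ in spec.lineage}
    leaves = [c for c in clusters if c not in has_child]
    anchors = [(root, 0.55)] + [(h, 0.45) for h in hubs] + [(l, 0.55) for l in leaves]
    per = max(1, 600 // len(anchors))
    table: dict[str, tuple[list[float], int]] = {}
    for a, rho in anchors:
        table[f"M_{a}"] = ([rho ** dist[a][c] for c in clusters], per)
    return table


@dataclass
class SimulationResult:
    expression: ExpressionMatrix
    labels: ClusterTable
    pathways: PathwayCollection
    truth: LabeledGraph
    program_activity: dict[str, dict[str, float]]  # program -> cluster -> activity
    compositions: dict[str, np.ndarray]            # realized per-cluster fractions

    def as_tuple(self):
        return self.expression, self.labels, self.pathways, self.truth


def _integer_composition(p: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` cells to time points."""
    raw = p * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def simulate(spec: SimulationSpec | None = None) -> SimulationResult:
    """Draw one data set from the planted-lineage model.

    Returns the expression matrix, per-cell labels, the program gene sets
    (plus decoy sets of background genes, so the pathway collection is not
    perfectly informative), and the true lineage as a gold-standard graph.
    """
    spec = spec or SimulationSpec()
    if spec.n_timepoints < 2:
        raise ValueError("need >= 2 time points")
    clusters = spec.clusters()
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_timepoints
    depths = spec.depths()
    max_depth = max(depths.values()) or 1

    # --- time compositions: kernel peaked at the cluster's lineage depth.
    # Cell counts are apportioned exactly and the stored composition is the
    # realized fraction, so temporal scores recomputed from emitted labels
    # match the spec exactly.
    compositions: dict[str, np.ndarray] = {}
    cell_counts: dict[str, np.ndarray] = {}
    times = np.arange(1, n + 1, dtype=float)
    for k in clusters:
        mu = 1.0 + depths[k] * (n - 1) / max_depth
        w = np.exp(-((times - mu) ** 2) / (2 * spec.composition_width**2))
        counts = _integer_composition(w / w.sum(), spec.cells_per_cluster)
        cell_counts[k] = counts
        compositions[k] = counts / counts.sum()

    # --- program activities from the module table ---
    lo, hi = spec.warp_range
    progs: list[str] = []
    patterns: list[np.ndarray] = []
    for mod_name, (pattern, count) in spec.module_table().items():
        base = np.asarray(pattern, dtype=float)
        if len(base) != len(clusters):
            raise ValueError(
                f"module {mod_name!r} pattern has {len(base)} entries for "
                f"{len(clusters)} clusters"
            )
        for r in range(count):
            warp = rng.uniform(lo, hi)
            amp = np.exp(rng.normal(0.0, spec.amplitude_sd))
            jit = rng.normal(0.0, spec.pattern_jitter, len(clusters))
            patterns.append(amp * (base**warp + jit))
            progs.append(f"{mod_name}_{r + 1:03d}")
    activity_matrix = np.array(patterns)  # programs x clusters
    activity = {
        prog: {k: float(activity_matrix[m, j]) for j, k in enumerate(clusters)}
        for m, prog in enumerate(progs)
    }

    # --- gene space and cluster mean matrix ---
    n_programs = len(progs)
    n_prog_genes = n_programs * spec.genes_per_program
    n_genes = n_prog_genes + spec.background_genes
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    mean = np.full((n_genes, len(clusters)), spec.mu0)
    for j in range(len(clusters)):
        mean[:n_prog_genes, j] += spec.delta * np.repeat(
            activity_matrix[:, j], spec.genes_per_program
        )

    # --- cells ---
    cell_ids: list[str] = []
    cell_cluster: dict[str, str] = {}
    cell_time: dict[str, int] = {}
    blocks: list[np.ndarray] = []
    for j, k in enumerate(clusters):
        noise = rng.normal(0.0, spec.sigma, size=(n_genes, spec.cells_per_cluster))
        blocks.append(mean[:, [j]] + noise)
        c = 0
        for i, cnt in enumerate(cell_counts[k], start=1):
            for _ in range(cnt):
                cid = f"{k}_cell{c:03d}"
                cell_ids.append(cid)
                cell_cluster[cid] = k
                cell_time[cid] = i
                c += 1
    values = np.concatenate(blocks, axis=1)
    expr = ExpressionMatrix(values, gene_ids, cell_ids)
    labels = ClusterTable(
        cell_to_cluster=cell_cluster,
        cell_to_timepoint=cell_time,
        timepoint_labels=[f"T{i}" for i in range(1, n + 1)],
    )

    # --- gene sets: the true programs plus decoys of background genes ---
    sets: dict[str, frozenset[str]] = {
        prog: frozenset(
            gene_ids[m * spec.genes_per_program:(m + 1) * spec.genes_per_program]
        )
        for m, prog in enumerate(progs)
    }
    background = gene_ids[n_prog_genes:]
    for d in range(spec.n_decoy_sets):
        pick = rng.choice(len(background), size=min(spec.decoy_set_size, len(background)),
                          replace=False)
        sets[f"DECOY_{d + 1:02d}"] = frozenset(background[i] for i in sorted(pick))
    pathways = PathwayCollection(sets, provenance=f"simulated(seed={spec.seed})")

    truth = LabeledGraph(
        nodes=list(clusters),
        edges=[(u, v, "forward") for u, v in spec.lineage],
    )
    return SimulationResult(expr, labels, pathways, truth, activity, compositions)
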