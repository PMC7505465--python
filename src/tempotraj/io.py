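"""Input parsing, core data types, and cluster summarisation.

The pipeline consumes three user-supplied inputs: a normalised gene x cell
expression matrix, per-cell cluster and time-point labels, and pathway gene
sets in GMT format.  Everything downstream works on per-cluster summaries:
the centroid (mean expression over member cells) and the time composition
(fraction of the cluster's cells collected at each time point).

The matrix is assumed normalised and log-scaled upstream; no re-normalisation
is ever applied here.  Centroids are averaged on the scale of the input
matrix as given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix, issparse


class DataError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Normalised gene x cell expression values with row/column identifiers.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` float array. Sparse input is densified
        on construction; the matrices involved downstream are per-cluster
        summaries, so memory is dominated by this one array.
    gene_ids, cell_ids
        Unique row and column identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if issparse(self.values):
            self.values = np.asarray(self.values.todense(), dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class ClusterTable:
    """Per-cell cluster assignment and ordinal time-point index.

    Time points are mapped to a contiguous ordinal range ``1..N`` following
    the collection order given by ``timepoint_labels``; label text is opaque
    (``"E11.5"`` is never parsed).
    """

    cell_to_cluster: dict[str, str]
    cell_to_timepoint: dict[str, int]
    timepoint_labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.timepoint_labels)
        _check_unique(self.timepoint_labels, "time point label")
        seen = sorted(set(self.cell_to_timepoint.values()))
        if any(i < 1 or i > n for i in seen):
            raise DataError(f"time indices {seen} outside 1..{n}")
        if set(self.cell_to_cluster) != set(self.cell_to_timepoint):
            raise DataError("cluster and time-point labels cover different cells")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoint_labels)

    @property
    def cluster_ids(self) -> list[str]:
        # first-appearance order over cells for determinism
        out: list[str] = []
        for c in self.cell_to_cluster.values():
            if c not in out:
                out.append(c)
        return out

    def reversed_time(self) -> "ClusterTable":
        """Return a copy with the time-label order reversed (i -> N+1-i)."""
        n = self.n_timepoints
        return ClusterTable(
            cell_to_cluster=dict(self.cell_to_cluster),
            cell_to_timepoint={c: n + 1 - i for c, i in self.cell_to_timepoint.items()},
            timepoint_labels=list(reversed(self.timepoint_labels)),
        )


@dataclass
class ClusterProfile:
    """Summary of one cluster: centroid expression and time composition.

    ``composition[i-1]`` is the fraction of the cluster's cells collected at
    time point ``i`` (fractions, not percent; they sum to one).
    """

    cluster_id: str
    centroid: np.ndarray
    composition: np.ndarray
    n_cells: int = 0

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.composition = np.asarray(self.composition, dtype=float)
        if not np.isclose(self.composition.sum(), 1.0, atol=1e-9):
            raise DataError(
                f"composition of cluster {self.cluster_id!r} sums to "
                f"{self.composition.sum()}, expected 1"
            )
        if np.any(self.composition < -1e-12) or np.any(self.composition > 1 + 1e-12):
            raise DataError(f"composition of cluster {self.cluster_id!r} outside [0,1]")


@dataclass
class PathwayCollection:
    """Named gene sets, size-filtered against the data's gene universe."""

    pathways: dict[str, frozenset[str]]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.items())

    def names(self) -> list[str]:
        return list(self.pathways)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    if dups:
        raise DataError(f"duplicate {kind} ids: {', '.join(map(repr, dups[:10]))}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from dense TSV/CSV or MatrixMarket triplet.

    Dense files have genes in rows, a header of cell ids, and the gene id in
    the first column.  MatrixMarket input expects sidecar ``genes.tsv`` and
    ``barcodes.tsv`` files next to the ``.mtx`` file (one id per line,
    first column used), following the common cellranger-style layout.

    Parameters
    ----------
    path
        File to read.
    format
        ``"dense_tsv"`` or ``"matrix_market"``; inferred from the suffix
        when omitted (``.mtx`` -> MatrixMarket, anything else dense).
    """
    path = Path(path)
    if format is None:
        format = "matrix_market" if path.suffix == ".mtx" else "dense_tsv"
    if format == "dense_tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError:
            for j, col in enumerate(df.columns):
                bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
                if bad.any():
                    i = int(np.argmax(bad.to_numpy()))
                    raise DataError(
                        f"non-numeric entry at row {df.index[i]!r}, column {col!r}"
                    ) from None
            raise
        return ExpressionMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))
    if format == "matrix_market":
        genes_path = path.parent / "genes.tsv"
        cells_path = path.parent / "barcodes.tsv"
        for p in (genes_path, cells_path):
            if not p.exists():
                raise DataError(f"missing sidecar file {p}")
        mat = mmread(path)
        genes = [ln.split("\t")[0].strip() for ln in genes_path.read_text().splitlines() if ln.strip()]
        cells = [ln.split("\t")[0].strip() for ln in cells_path.read_text().splitlines() if ln.strip()]
        return ExpressionMatrix(mat, genes, cells)
    raise ValueError(f"unknown format {format!r}")


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "dense_tsv") -> None:
    """Write an expression matrix (dense TSV/CSV or .mtx with sidecars)."""
    path = Path(path)
    if format == "dense_tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        expr.to_frame().to_csv(path, sep=sep)
    elif format == "matrix_market":
        mmwrite(str(path), coo_matrix(expr.values))
        (path.parent / "genes.tsv").write_text("\n".join(expr.gene_ids) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(expr.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | Path, timepoint_order: Sequence[str] | None = None) -> ClusterTable:
    """Read per-cell labels from a TSV with columns cell_id, cluster, time_label.

    ``timepoint_order`` fixes the ordinal mapping of time labels; when omitted
    the order of first appearance in the file is used (a warning notes this,
    since collection order is a scientific input, not a file-layout accident).
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 3:
        raise DataError(f"label table {path} needs >= 3 columns (cell, cluster, time)")
    cells = df.iloc[:, 0].tolist()
    _check_unique(cells, "cell")
    clusters = df.iloc[:, 1].tolist()
    times = df.iloc[:, 2].tolist()
    if timepoint_order is None:
        timepoint_order = list(dict.fromkeys(times))
        warnings.warn(
            "time-point order taken from first appearance in the label file; "
            "pass timepoint_order explicitly if collection order differs",
            stacklevel=2,
        )
    order = {t: i + 1 for i, t in enumerate(timepoint_order)}
    missing = sorted(set(times) - set(order))
    if missing:
        raise DataError(f"time labels {missing} absent from timepoint_order")
    return ClusterTable(
        cell_to_cluster=dict(zip(cells, clusters)),
        cell_to_timepoint={c: order[t] for c, t in zip(cells, times)},
        timepoint_labels=list(timepoint_order),
    )


def write_labels(labels: ClusterTable, path: str | Path) -> None:
    rows = [
        (c, labels.cell_to_cluster[c], labels.timepoint_labels[labels.cell_to_timepoint[c] - 1])
        for c in labels.cell_to_cluster
    ]
    pd.DataFrame(rows, columns=["cell_id", "cluster", "time_label"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(
    path: str | Path,
    min_size: int = 10,
    max_size: int = 500,
    gene_universe: Iterable[str] | None = None,
    ignore_case: bool = False,
) -> PathwayCollection:
    """Parse a GMT file and size-filter gene sets against the gene universe.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Sets are
    intersected with ``gene_universe`` *before* the ``[min_size, max_size]``
    filter, so the size bound refers to genes actually measured in the data:
    a 400-gene set with 2 measured members carries no usable signal and is
    dropped rather than scored.  Gene matching is case-sensitive by default
    (symbol case conventions are species-specific); ``ignore_case`` maps
    everything through upper case.
    """
    path = Path(path)
    universe = None
    if gene_universe is not None:
        universe = {g.upper() for g in gene_universe} if ignore_case else set(gene_universe)
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            name = fields[0]
            genes = {g.strip() for g in fields[2:] if g.strip()}
            if ignore_case:
                genes = {g.upper() for g in genes}
            if name in pathways:
                raise DataError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if universe is not None:
                genes &= universe
            if min_size <= len(genes) <= max_size:
                pathways[name] = frozenset(genes)
    if not pathways:
        warnings.warn(f"no gene sets from {path} survived the size filter", stacklevel=2)
    return PathwayCollection(pathways, provenance=str(path))


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# cluster summarisation
# ---------------------------------------------------------------------------

def build_cluster_profiles(expr: ExpressionMatrix, labels: ClusterTable) -> list[ClusterProfile]:
    """Compute per-cluster centroids and time compositions.

    The centroid is the arithmetic mean of the member cells' expression
    columns on the scale of the input matrix.  Cluster order follows first
    appearance in the label table; both are independent of cell order.
    """
    missing = [c for c in expr.cell_ids if c not in labels.cell_to_cluster]
    if missing:
        raise DataError(f"{len(missing)} cells lack labels, e.g. {missing[:5]}")
    n = labels.n_timepoints
    col = {c: j for j, c in enumerate(expr.cell_ids)}
    profiles: list[ClusterProfile] = []
    for k in labels.cluster_ids:
        members = [c for c in expr.cell_ids if labels.cell_to_cluster[c] == k]
        if not members:
            continue
        idx = [col[c] for c in members]
        centroid = expr.values[:, idx].mean(axis=1)
        counts = np.zeros(n)
        for c in members:
            counts[labels.cell_to_timepoint[c] - 1] += 1
        profiles.append(
            ClusterProfile(k, centroid, counts / counts.sum(), n_cells=len(members))
        )
    return profiles


def centroid_frame(profiles: Sequence[ClusterProfile], gene_ids: Sequence[str]) -> pd.DataFrame:
    """Stack centroids into a genes x clusters DataFrame."""
    return pd.DataFrame(
        np.column_stack([p.centroid for p in profiles]),
        index=list(gene_ids),
        columns=[p.cluster_id for p in profiles],
    )
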