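"""End-to-end trajectory inference: centroids -> enrichment -> PCA ->
MI network -> temporal orientation.

`run_pipeline` is the programmatic face of the whole method; the CLI and
the example scripts are thin wrappers around it.  Intermediate products
(cluster profiles, enrichment matrix, PCA reduction, MI network) are kept
on the result object so each stage can be inspected or cached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationResult, EnrichmentMatrix, annotate_clusters, enrich
from .io import (
    ClusterProfile,
    ClusterTable,
    ExpressionMatrix,
    PathwayCollection,
    build_cluster_profiles,
    centroid_frame,
)
from .network import MINetwork, build_network
from .ordering import TrajectoryGraph, orient, scores_from_profiles
from .reduction import ReductionResult, reduce


@dataclass
class PipelineResult:
    profiles: list[ClusterProfile]
    enrichment: EnrichmentMatrix | None
    reduction: ReductionResult | None
    mi_profiles: pd.DataFrame
    network: MINetwork
    trajectory: TrajectoryGraph
    annotation: AnnotationResult | None = None

    def write_cache(self, outdir: str | Path) -> None:
        """Write every intermediate as TSV for reproducibility."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        comp = pd.DataFrame(
            {p.cluster_id: p.composition for p in self.profiles}
        ).T
        comp.columns = [f"time_{i + 1}" for i in range(comp.shape[1])]
        comp.to_csv(outdir / "compositions.tsv", sep="\t")
        if self.enrichment is not None:
            self.enrichment.to_tsv(outdir / "enrichment.tsv")
        if self.reduction is not None:
            self.reduction.write_scree(outdir / "scree.tsv")
            pd.Series(self.reduction.selected_pathways).to_csv(
                outdir / "selected_pathways.tsv", sep="\t", index=False, header=False
            )
        self.network.write_tsv(outdir / "mi_network.tsv")
        self.trajectory.write_tsv(outdir / "trajectory.tsv")
        self.trajectory.write_dot(outdir / "trajectory.dot")


def run_pipeline(
    expr: ExpressionMatrix,
    labels: ClusterTable,
    pathways: PathwayCollection | None,
    n_pcs: int,
    loading_threshold: float = 0.4,
    similarity_threshold: float = 0.01,
    similarity_mode: str = "relative",
    dpi_tolerance: float = 0.0,
    use_enrichment: bool = True,
    mi_space: str = "pathways",
    marker_sets: PathwayCollection | None = None,
    min_mi_features: int = 8,
) -> PipelineResult:
    """Infer a directed cluster trajectory from time-series expression data.

    Parameters
    ----------
    expr, labels
        Normalized expression matrix and per-cell cluster/time labels.
    pathways
        Gene sets for the enrichment transform (ignored when
        ``use_enrichment`` is False).
    n_pcs
        Number of leading principal components for pathway selection,
        chosen by the user from the scree output.
    loading_threshold
        Absolute-loading cut for pathway selection (default 0.4).
    similarity_threshold, similarity_mode
        Near-tie rule for leaving edges undirected.
    dpi_tolerance
        Data-processing-inequality pruning tolerance (0 = strict).
    use_enrichment
        When False (ablation), the MI network is built directly on gene-
        space centroids and the enrichment/PCA stages are skipped.
    mi_space
        ``"pathways"`` (MI over the selected pathway enrichment rows,
        default) or ``"pc"`` (MI over principal-component coordinates).
    marker_sets
        Optional marker gene sets for cell-type annotation of clusters.
    min_mi_features
        The MI estimator needs at least this many features per profile;
        if the loading threshold selects fewer pathways, the selection is
        topped up with the next-highest-loading pathways (with a warning).
    """
    profiles = build_cluster_profiles(expr, labels)
    centroids = centroid_frame(profiles, expr.gene_ids)
    enrichment_matrix: EnrichmentMatrix | None = None
    red: ReductionResult | None = None
    if use_enrichment:
        if pathways is None or len(pathways) == 0:
            raise ValueError("pathway collection required when use_enrichment=True")
        enrichment_matrix = enrich(centroids, pathways)
        k = len(profiles)
        p = len(enrichment_matrix.pathway_names)
        n_pcs_eff = min(n_pcs, min(p, k - 1))
        if n_pcs_eff < n_pcs:
            warnings.warn(
                f"n_pcs={n_pcs} exceeds attainable rank; using {n_pcs_eff}",
                stacklevel=2,
            )
        red = reduce(enrichment_matrix, n_pcs_eff, loading_threshold)
        if mi_space == "pc":
            mi_profiles = red.pc_scores.T.iloc[:n_pcs_eff]
        elif mi_space == "pathways":
            selected = list(red.selected_pathways)
            if len(selected) < min_mi_features:
                ranking = (
                    red.loadings.iloc[:, :n_pcs_eff].abs().max(axis=1).sort_values(ascending=False)
                )
                extra = [n for n in ranking.index if n not in selected]
                need = min(min_mi_features, p) - len(selected)
                selected = selected + extra[:need]
                warnings.warn(
                    f"loading threshold selected {len(red.selected_pathways)} pathways; "
                    f"topped up to {len(selected)} to keep the MI estimator defined",
                    stacklevel=2,
                )
            mi_profiles = enrichment_matrix.scores.loc[selected]
        else:
            raise ValueError(f"unknown mi_space {mi_space!r}")
    else:
        mi_profiles = centroids
    net = build_network(mi_profiles, dpi_tolerance=dpi_tolerance)
    scores = scores_from_profiles(profiles)
    annotation = None
    annotations_map: Mapping[str, str] | None = None
    if marker_sets is not None and len(marker_sets) > 0:
        annotation = annotate_clusters(centroids, marker_sets)
        annotations_map = annotation.labels
    traj = orient(
        net,
        scores,
        similarity_threshold=similarity_threshold,
        similarity_mode=similarity_mode,
        annotations=annotations_map,
    )
    return PipelineResult(
        profiles=profiles,
        enrichment=enrichment_matrix,
        reduction=red,
        mi_profiles=mi_profiles,
        network=net,
        trajectory=traj,
        annotation=annotation,
    )
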