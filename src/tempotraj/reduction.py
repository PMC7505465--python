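"""PCA-based redundancy reduction of pathway enrichment profiles.

Pathway databases are redundant (well-studied processes appear under many
names), so the enrichment matrix is compressed with PCA before network
construction: the user picks the number of leading components from a scree
plot, and pathways with at least one absolute loading above a threshold
(default 0.4, a common factor-analysis rule of thumb) on those components
are retained as the informative, non-redundant subset.

Loadings follow the factor-analysis convention the 0.4 rule of thumb comes
from: the correlation between each pathway's scores and each component
(eigenvector entries scaled by the component's standard deviation and the
pathway's own standard deviation), so they live in [-1, 1] and any number
of mutually redundant informative pathways can pass the cut together.
Unit-norm eigenvector loadings are available as an option, but note that at
threshold t at most ``floor(1/t^2)`` pathways per component can exceed an
eigenvector loading of t, which starves the downstream mutual-information
estimator on redundant databases.

The PCA is deterministic: full SVD on pathway-centred scores with a fixed
sign convention, no scaling (enrichment scores already share a bounded
scale, and scaling would promote flat noisy pathways to parity with
informative ones).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ReductionResult:
    """PCA of the enrichment matrix plus the loading-thresholded selection."""

    pc_scores: pd.DataFrame        # clusters x components
    loadings: pd.DataFrame         # pathways x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    selected_pathways: list[str]
    n_components: int
    loading_threshold: float

    def scree_frame(self) -> pd.DataFrame:
        """Component index vs variance, for the user's elbow inspection."""
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.explained_variance) + 1),
                "variance": self.explained_variance,
                "variance_ratio": self.explained_variance_ratio,
            }
        )

    def write_scree(self, path: str | Path) -> None:
        self.scree_frame().to_csv(path, sep="\t", index=False)


def reduce(
    E,
    n_components: int,
    loading_threshold: float = 0.4,
    loadings: str = "correlation",
) -> ReductionResult:
    """PCA on pathway-centred enrichment scores and loading-based selection.

    Parameters
    ----------
    E
        EnrichmentMatrix (pathways x clusters).  Clusters are the
        observations; each pathway is a feature centred across clusters.
    n_components
        Number of leading components the user chose from the scree plot.
        Must not exceed the attainable rank ``min(P, K-1)``.
    loading_threshold
        A pathway is selected when ``max_j |loading(p, j)| > threshold``
        over the first ``n_components`` components.
    loadings
        ``"correlation"`` (pathway-component correlations, the
        factor-analysis convention, default) or ``"eigenvector"``
        (unit-norm component vectors).
    """
    scores = E.scores
    X = scores.to_numpy().T  # clusters x pathways
    k, p = X.shape
    Xc = X - X.mean(axis=0, keepdims=True)
    rank = int(np.linalg.matrix_rank(Xc))
    if n_components > min(p, k - 1):
        raise ValueError(
            f"n_components={n_components} exceeds attainable rank "
            f"min(P={p}, K-1={k - 1}) = {min(p, k - 1)}"
        )
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fixed sign convention: largest-|value| element of each component positive
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    explained = s**2 / (k - 1)
    comp_names = [f"PC{j + 1}" for j in range(len(s))]
    load = Vt.T.copy()  # pathways x components, unit-norm columns
    if loadings == "correlation":
        sd_path = Xc.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            load = load * np.sqrt(explained)[None, :] / sd_path[:, None]
        load[sd_path == 0, :] = 0.0  # constant pathway: no correlation
    elif loadings != "eigenvector":
        raise ValueError(f"unknown loadings convention {loadings!r}")
    load_df = pd.DataFrame(load, index=scores.index, columns=comp_names)
    pc_df = pd.DataFrame(U * s, index=scores.columns, columns=comp_names)
    top = np.abs(load[:, :n_components]).max(axis=1)
    selected = [name for name, t in zip(scores.index, top) if t > loading_threshold]
    return ReductionResult(
        pc_scores=pc_df,
        loadings=load_df,
        explained_variance=explained,
        explained_variance_ratio=explained / explained.sum() if explained.sum() else explained,
        selected_pathways=selected,
        n_components=n_components,
        loading_threshold=loading_threshold,
    )


def plot_scree(result: ReductionResult, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    sf = result.scree_frame()
    ax.plot(sf["component"], sf["variance"], "o-")
    ax.axvline(result.n_components + 0.5, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("principal component")
    ax.set_ylabel("variance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
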