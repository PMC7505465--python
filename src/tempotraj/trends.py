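"""Time-dependent pathway detection along the trajectory.

For every pathway, enrichment scores across clusters are regressed on the
cluster temporal score with a penalized cubic B-spline smoother (a small
Gaussian generalized additive model, one observation per cluster) and
compared against the null model of uniform enrichment over time
(intercept only) by an approximate F-test that uses the effective degrees
of freedom of the penalized fit.  P-values are Benjamini-Hochberg adjusted
across all tested pathways; pathways below the adjusted threshold (default
0.05) are reported as significantly time-varying.

By default the spline is unpenalized (a regression spline with a small
basis), which makes the F-test exact under Gaussian noise; a fixed
smoothing penalty or per-pathway generalized cross-validation can be
requested instead (an extreme penalty shrinks the fit to the null model
and the p-value to 1; GCV selection on the same data inflates the
approximate test and is offered for exploratory smoothing only).  Fits for
all pathways share the same design, so the smoother matrices are built
once per penalty value and applied to the whole enrichment matrix at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist
from statsmodels.gam.smooth_basis import BSplines
from statsmodels.stats.multitest import multipletests

from .enrichment import EnrichmentMatrix

_ALPHA_GRID = np.logspace(-4.0, 6.0, 21)


@dataclass
class TrendResult:
    """Fit and test of one pathway's enrichment trend over temporal score."""

    pathway_name: str
    p_value: float
    adjusted_p: float
    significant: bool
    curve: pd.DataFrame  # columns: T, enrichment, fitted, ci_lower, ci_upper
    edf: float
    penalty: float
    flag: str = ""  # "", "constant", "degenerate"


def _spline_design(x: np.ndarray, basis_df: int) -> tuple[np.ndarray, np.ndarray]:
    """Intercept + B-spline design matrix and its block penalty matrix.

    The penalty is the curvature penalty plus a small multiple of the
    identity on the spline block, so that infinite smoothing shrinks the
    fit all the way to the intercept-only null (a pure curvature penalty
    would stop at a linear fit, whose null space it spans).
    """
    degree = 3 if basis_df >= 4 else max(1, basis_df - 1)
    smoother = BSplines(x, df=[basis_df], degree=[degree], include_intercept=False)
    basis = smoother.basis
    design = np.column_stack([np.ones(len(x)), basis])
    curv = smoother.penalty_matrices[0]
    scale = np.trace(curv) / curv.shape[0] or 1.0
    pen = np.zeros((design.shape[1], design.shape[1]))
    pen[1:, 1:] = curv + 1e-3 * scale * np.eye(curv.shape[0])
    return design, pen


def _hat_matrix(design: np.ndarray, pen: np.ndarray, alpha: float) -> np.ndarray:
    xtx = design.T @ design + alpha * pen
    return design @ np.linalg.solve(xtx, design.T)


def trend_pvalues(
    Y: np.ndarray,
    x: np.ndarray,
    penalty: float | str = 0.0,
    basis_df: int | None = None,
) -> dict[str, np.ndarray]:
    """Array-level core of the trend test (shared by `detect_trends` and
    calibration simulations).

    Parameters
    ----------
    Y
        Clusters x pathways response matrix.
    x
        Cluster temporal scores, length = rows of ``Y``.

    Returns a dict with ``p`` (raw p-values), ``edf``, ``penalty``,
    ``fitted`` (clusters x pathways), ``sigma2`` and ``flags`` per pathway.
    All pathways share the design, so smoother matrices are built once per
    candidate penalty and applied to the whole matrix.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    k = len(x)
    if Y.shape[0] != k:
        raise ValueError("Y rows must match the number of cluster scores")
    if len(np.unique(x)) < 4:
        raise ValueError("trend fitting needs >= 4 clusters with distinct scores")
    if basis_df is None:
        basis_df = min(k - 1, 5)
    design, pen = _spline_design(x, basis_df)
    n_path = Y.shape[1]
    ybar = Y.mean(axis=0, keepdims=True)
    rss0 = ((Y - ybar) ** 2).sum(axis=0)

    alphas = _ALPHA_GRID if penalty == "gcv" else np.array([float(penalty)])
    gcv = np.full((len(alphas), n_path), np.inf)
    fits = np.empty((len(alphas), k, n_path))
    edfs = np.empty(len(alphas))
    for i, a in enumerate(alphas):
        H = _hat_matrix(design, pen, a)
        edfs[i] = float(np.trace(H))
        fits[i] = H @ Y
        rss = ((Y - fits[i]) ** 2).sum(axis=0)
        denom = k - edfs[i]
        if denom > 1e-8:
            gcv[i] = k * rss / denom**2
    best = np.argmin(gcv, axis=0)

    raw_p = np.ones(n_path)
    flags = np.array([""] * n_path, dtype=object)
    edf_used = edfs[best]
    fitted = np.empty((k, n_path))
    sigma2 = np.zeros(n_path)
    for j in range(n_path):
        i = int(best[j])
        fitted[:, j] = fits[i, :, j]
        rss1 = float(((Y[:, j] - fitted[:, j]) ** 2).sum())
        df_num = edfs[i] - 1.0
        df_den = k - edfs[i]
        if rss0[j] <= 1e-24:
            flags[j] = "constant"
            fitted[:, j] = Y[:, j].mean()
            continue
        if df_den <= 1e-8 or not np.isfinite(rss1):
            flags[j] = "degenerate"
            continue
        if df_num < 0.05:
            # smoothing collapsed the fit onto the null: no evidence either way
            continue
        sigma2[j] = rss1 / df_den
        fstat = max(rss0[j] - rss1, 0.0) / df_num / max(sigma2[j], 1e-300)
        raw_p[j] = float(f_dist.sf(fstat, df_num, df_den))
    return {
        "p": raw_p,
        "edf": edf_used,
        "penalty": alphas[best],
        "penalty_index": best,
        "alphas": alphas,
        "fitted": fitted,
        "sigma2": sigma2,
        "flags": flags,
        "design": design,
        "pen": pen,
    }


def detect_trends(
    E: EnrichmentMatrix,
    scores: Mapping[str, float],
    alpha: float = 0.05,
    penalty: float | str = 0.0,
    basis_df: int | None = None,
) -> list[TrendResult]:
    """Test every pathway for enrichment variation over the trajectory.

    Parameters
    ----------
    E
        Full pathway x cluster enrichment matrix (all pathways are tested,
        not only the PCA-selected subset).
    scores
        Temporal score per cluster (the x-axis; ties are legal).
    alpha
        Adjusted-p significance threshold.
    penalty
        Fixed non-negative smoothing penalty (default 0: an unpenalized
        regression spline, for which the F-test is exact) or ``"gcv"``
        for per-pathway generalized cross-validation.  Note that choosing
        the penalty by GCV and testing on the same data inflates the
        type-I error of the approximate F-test; the unpenalized default
        keeps the test calibrated.
    basis_df
        Spline basis dimension; default ``min(K - 1, 5)``.

    Returns results sorted by adjusted p-value.  A pathway whose fit is
    degenerate (constant enrichment, singular design) is reported with
    p = 1 and a flag, never dropped.
    """
    clusters = E.cluster_ids
    x = np.array([scores[c] for c in clusters], dtype=float)
    k = len(x)
    Y = E.scores.to_numpy().T  # clusters x pathways
    core = trend_pvalues(Y, x, penalty=penalty, basis_df=basis_df)
    raw_p = core["p"]
    _, adj_p, _, _ = multipletests(raw_p, method="fdr_bh")
    design, pen = core["design"], core["pen"]
    # hat-matrix diagonal of H H^T per selected penalty, for CI bands
    hdiag = {
        int(i): np.maximum(
            np.diag(
                _hat_matrix(design, pen, float(core["alphas"][i]))
                @ _hat_matrix(design, pen, float(core["alphas"][i])).T
            ),
            0.0,
        )
        for i in np.unique(core["penalty_index"])
    }
    results: list[TrendResult] = []
    for j, name in enumerate(E.pathway_names):
        i = int(core["penalty_index"][j])
        se = np.sqrt(hdiag[i] * core["sigma2"][j])
        df_den = max(k - core["edf"][j], 1.0)
        tq = float(t_dist.ppf(0.975, df_den))
        fitted = core["fitted"][:, j]
        curve = pd.DataFrame(
            {
                "T": x,
                "enrichment": Y[:, j],
                "fitted": fitted,
                "ci_lower": fitted - tq * se,
                "ci_upper": fitted + tq * se,
            },
            index=clusters,
        ).sort_values("T")
        results.append(
            TrendResult(
                pathway_name=name,
                p_value=float(raw_p[j]),
                adjusted_p=float(adj_p[j]),
                significant=bool(adj_p[j] < alpha),
                curve=curve,
                edf=float(core["edf"][j]),
                penalty=float(core["penalty"][j]),
                flag=str(core["flags"][j]),
            )
        )
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.pathway_name))
    return results


def trend_table(results: Sequence[TrendResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway_name for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "significant": [r.significant for r in results],
            "edf": [r.edf for r in results],
            "flag": [r.flag for r in results],
        }
    )


def plot_trend(result: TrendResult, out: str | Path) -> None:
    """Scatter of cluster scores vs enrichment with fit and 95% CI band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    c = result.curve
    ax.fill_between(c["T"], c["ci_lower"], c["ci_upper"], color="0.85")
    ax.plot(c["T"], c["fitted"], color="black")
    ax.scatter(c["T"], c["enrichment"], color="tab:blue", zorder=3)
    ax.set_xlabel("temporal score")
    ax.set_ylabel("enrichment")
    ax.set_title(f"{result.pathway_name}\nadj. p = {result.adjusted_p:.3g}", fontsize=9)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
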