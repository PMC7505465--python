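# Methods

This note records the model, the defaults and the judgement calls behind
`tempotraj`, at the level of detail a user would need to trust or modify
the pipeline.

## Model and assumptions

The pipeline treats a time-series scRNA-seq experiment as a set of K cell
clusters observed over N ordered collection times. Two assumptions carry
all inference:

1. **Similarity ⇒ lineage proximity.** Clusters with similar
   pathway-enrichment profiles are close in the underlying lineage. The
   mutual-information network plus data-processing-inequality (DPI)
   pruning turns this into a sparse undirected graph: in every triangle
   the weakest edge is presumed indirect and removed.
2. **Differentiation moves forward in time.** A cluster's temporal score
   `T = Σ pᵢ·i` (composition-weighted mean ordinal collection time)
   orders every edge early → late. The method therefore cannot represent
   dedifferentiation; edges between clusters with nearly equal scores are
   deliberately left undirected rather than oriented on noise.

Clustering, normalization and batch correction are upstream concerns: the
input matrix is taken as given (assumed normalized, roughly log-scale)
and is never re-normalized; centroids are averaged on the input scale.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| GMT size bounds | 10–500 genes | gene sets outside this range are uninformative or too generic; sizes are counted **after** intersecting with the measured genes, so the bound refers to usable genes |
| kernel bandwidth | sd/4 per gene | Gaussian-kernel CDF across clusters; the standard choice for the enrichment statistic |
| ES convention | magnitude difference | sum of the extreme positive and negative walk deviations; `max_deviation` available |
| walk weight τ | 1 | linear weighting of centred ranks; not exposed further |
| n. principal components | user-chosen (scree) | never auto-selected; the scree table/plot is emitted for inspection |
| loading threshold | 0.4 | factor-analysis rule of thumb, applied to pathway–component **correlations**; with unit-norm eigenvector loadings at most ⌊1/0.4²⌋ = 6 pathways per component could ever pass, which starves the MI estimator, so the correlation convention is the default and eigenvectors an option |
| MI bins | ⌊√m⌋ (min 2) | m = number of selected pathways; equal-frequency binning of ranks, plug-in estimator, nats |
| DPI tolerance | 0 (strict) | exact triangle minima are removed; ties are removed together (conservative, deterministic) |
| similarity threshold | 0.01 relative | `|T_a−T_b|/max(T_a,T_b) < 0.01` ⇒ dashed; an absolute mode exists |
| trend basis | min(K−1, 5) params | cubic B-spline + intercept; one observation per cluster |
| trend penalty | 0 | unpenalized regression spline ⇒ the F-test against the intercept-only null is exact (measured type-I error 0.050 at the nominal 0.05); GCV selection is available but inflates the naive F-test to ≈0.12 and is flagged as exploratory |
| significance threshold | adjusted p < 0.05 | Benjamini–Hochberg across all tested pathways |

The MI estimator needs at least 8 features and is coarse below 25 (it
warns in both regimes); if the loading threshold selects fewer than 8
pathways the pipeline tops the selection up by loading rank and warns.

## Numerical choices

* Centred rank statistic `|rank − (G+1)/2|`: symmetric, so reversing a
  cluster's ranking exactly negates the enrichment score; reference
  implementations use the slightly asymmetric `|rank − G/2|` (observed
  difference ≤ 0.006 against an independent implementation).
* Ranking ties: average ranks for the weights, stable order by gene index
  for the walk — deterministic, at the cost of tiny asymmetries between
  identically-patterned genes.
* A gene constant across clusters gets kernel statistic 0.5 everywhere
  (all tied), never NaN. Constant profiles get MI 0 with a warning.
* PCA is full SVD with a fixed sign convention (largest-magnitude entry
  of each component made positive); pathways are centred across clusters
  and not scaled (enrichment scores already share a bounded scale).
* The spline penalty adds 1e-3 × identity to the curvature matrix so that
  infinite smoothing shrinks to the intercept rather than to a linear
  fit; fits that collapse onto the null report p = 1. Degenerate or
  constant pathways are reported with p = 1 and a flag, never dropped.
* Orientation, DPI, and all file outputs are pure functions of their
  inputs; reruns are bit-identical.

## What the simulator emulates — and what it does not

The generator plants a known lineage tree (default: six clusters,
chain-plus-branch, four time points) and emits expression, labels, gene
sets and the true graph. Its design mirrors the transcriptional
organisation of tissue development: a stemness module declining with
lineage depth, a transient progenitor module peaking at the branch point,
and one differentiation ramp per branch with partial priming at the
progenitor. The two branches are deliberately asymmetric in module size,
priming and ramp speed — real branches are never mirror images, and exact
symmetry creates an artificial one-to-one correspondence between branch
profiles that inflates their mutual information. Each program perturbs
its module with a random monotone power warp, a log-normal amplitude and
small jitter, giving 600 diverse informative sets plus 20 decoys drawn
from background genes.

Two structural facts discovered while designing the generator are worth
recording. First, single-sample enrichment profiles are effectively
centred across clusters (pairwise profile correlations sum to ≈ −K/2), so
at small K no data set can make *correlation magnitude* decrease
monotonically with lineage distance — distant branches always acquire
negative correlation. Recovery therefore relies on adjacent clusters
being related by *tight* monotone maps (high mutual information) while
the centring-induced anti-correlations stay diffuse. Second, a
descendant-only "on/off" program design makes separate branches strongly
anti-correlated, which rank-based MI — being sign-blind — scores as
maximal dependence; graded, partially shared module activity is both more
realistic and necessary for the method's own assumption to hold.

Cell-level expression is Gaussian around cluster means on a log-like
scale (default effect δ = 2 per unit activity against noise σ = 0.5, 80
cells per cluster). Dropout, count noise, doublets and batch effects are
not modelled. Passing tests on this generator show that the pipeline's
inferential machinery recovers a lineage whose signal geometry matches
its assumptions; they do not certify performance on real data, where
clustering quality, pathway-database coverage and batch structure
dominate.

Measured under the default conditions (20 seeds): mean directed-edge F1
0.89, minimum 0.62, planted root recovered 20/20; `scripts/acceptance.py`
recomputes these numbers.

## Design choices where the design was open

* **MI feature space.** The network is built on the selected pathways'
  enrichment rows (not PC coordinates); `mi_space="pc"` exists but is
  only meaningful when enough components are kept to satisfy the MI
  estimator's feature minimum.
* **Similarity criterion.** "Similar temporal scores" is taken as a
  relative difference (matching a ">99 % similarity" reading of the 0.01
  default). Note the relative criterion is not exactly symmetric under
  time reversal for borderline pairs; the absolute mode is.
* **Trend null model.** "Uniform enrichment over time" is implemented as
  the intercept-only model, compared by an F-test using the effective
  degrees of freedom of the (optionally penalized) fit.
* **Evaluation granularity.** Gold standards live at cell-type level, so
  predicted clusters are collapsed by annotation label before scoring;
  parallel edges merge, and a pair predicted in both directions becomes
  one bidirectional edge. Each differing unordered label pair counts once
  in the mismatch score.
* **Cluster weighting.** Clusters enter the trend test unweighted (one
  point per cluster, regardless of size).

## Known limitations

* No per-cell pseudotime: the method is cluster-level by design, and
  gradual within-cluster transitions are invisible to it.
* The trend test has one observation per cluster; at K ≲ 6 clusters its
  power after multiple-testing correction over hundreds of pathways is
  low, and branch-specific programs (opposite enrichment at equal
  temporal score) are largely undetectable by a test indexed on `T`
  alone. Calibration is exact, power grows with K.
* Kernel density estimates across fewer than ~5 clusters are coarse (the
  enrichment step warns).
* The direction model assumes unidirectional differentiation; dashed
  edges mark where the data do not support a direction, not where the
  biology is bidirectional.
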