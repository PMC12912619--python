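# Methods

## Model and assumptions

The pipeline treats a subject's regional amyloid burden as a vector of
SUVR values over a fixed parcellation and models between-region
dependence at the group level as a Pearson-correlation ("covariance")
network.  Individual networks are defined by perturbation: the subject is
appended to the reference cohort, the correlation matrix is recomputed,
and the edge-wise change is standardized,

    z_ij = (CDN_ij − REN_ij) / ((1 − CDN_ij²) / (n − 1)),

with n the reference-group size.  The denominator is implemented exactly
as written (no square root); the standard-error variant
√((1 − CDN²)/(n − 1)) is available through
`perturbation_zscore(..., use_sqrt_denominator=True)` for sensitivity
analysis.  Off-diagonal correlations at |r| ≥ 1 − 1e−12 are clipped to
that bound before the denominator, with a per-edge warning, so outputs
stay finite (saturation rule).

Two properties of this statistic matter for interpretation and are
verified by the test suite:

* under the null (a subject drawn from the reference distribution) the
  edge-wise Z is centred on zero with roughly unit variance — the
  per-subject influence on a correlation is ≈ ψ/(n+1) with
  SD(ψ) = 1 − r², which the denominator undoes;
* the statistic responds to *any* atypicality of the added subject, not
  only to correlation differences: a subject whose regional means are
  shifted relative to the reference cohort inflates all pairwise products
  of deviations and hence shifts Z globally.  Mean effects and
  connectivity effects are therefore entangled at the network stage;
  experiments that target connectivity recovery must equalize group means
  (the synthetic recovery experiments do exactly this).

The Fisher transform (arctanh) is provided for correlation-valued
matrices only; applying it to a Z matrix is a domain error and is
rejected by a range check (arctanh is undefined beyond |r| = 1).  The
ordering of the transform relative to the Z-score is left to the caller
for this reason.

## Binarization

Only positive weights are eligible.  At sparsity s, the strongest
⌊s·M⌋ positive edges (M = R(R−1)/2) are kept; if fewer positive weights
exist, all of them are kept and a warning is emitted when there are none.
Ties are broken by (row, column) lexicographic order, making the
ensembles platform-independent.  Because thresholds select prefixes of a
single sorted edge list, edge sets are nested along the grid by
construction, and average degree and global efficiency are monotone in s.
The default grid is 0.05–0.35 in steps of 0.01 (31 thresholds); the
lower bound is fixed rather than estimated per dataset and is
configurable.

## Graph metrics

All metrics are computed in-package on 0/1 adjacency matrices: BFS
distances (simultaneous frontier expansion), Brandes betweenness
(reported both raw over unordered pairs and normalized by
(R−1)(R−2)/2; group statistics default to raw, the common toolbox
output), triangle-based clustering, and efficiencies from inverse
distances.  Disconnected graphs: the characteristic path length is the
mean over *connected* ordered pairs, with the infinite-pair fraction
reported and the affected thresholds excluded from that metric's AUC;
global/local efficiency, which handle disconnection gracefully, are the
primary disconnection-robust measures.

Small-world normalization uses Maslov–Sneppen double-edge swaps:
n_random = 100 rewired graphs per threshold, 10 swaps per edge
(defaults; both configurable).  Graphs with no valid swap (e.g. a
triangle) are returned unchanged with a warning.  With zero swaps the
ensemble is the graph itself and γ = λ = σ = 1 exactly, which anchors
the normalization tests.

Metrics are aggregated across the grid by the trapezoidal rule.  The
grid-AUC scale is the primary reported scale: with 26 nodes and the
default grid, average degree at sparsity s is 2⌊325·s⌋/26 ≈ 25·s, whose
integral over the 0.30-wide window is ≈ 1.5 — the magnitude on which
grid-AUC global metrics naturally live.

## Synthetic cohorts

Subjects are drawn from group-specific multivariate normal distributions.
Normality is the natural generative family because Pearson-correlation
networks fully characterize dependence under it.  Defaults reflect the
study conditions the package is designed for:

* group sizes 172/159/141/140 (CN/EMCI/LMCI/AD);
* compartment mean SUVR 0.55/0.58/0.60/0.63 (cerebellar) and
  0.62/0.70/0.78/0.88 (cortical), with a fixed deterministic ±0.04
  across-ROI gradient standing in for regional heterogeneity (per-ROI
  distributions are not published, so these are configuration, not
  fact);
* per-ROI SD 0.08, chosen so the per-subject compartment-mean spread
  matches published interquartile ranges (IQR ≈ 0.08 for the cerebellar
  mean);
* a two-factor correlation structure (one global factor, one per
  compartment; within-compartment r ≈ 0.61, across ≈ 0.49), reflecting
  the strong inter-regional covariance of amyloid burden;
* demographics (age, MMSE, sex ratios) drawn per group from the
  published baseline moments, independent of SUVR by default; an
  optional age slope couples SUVR to age so covariate adjustment has a
  nonzero ground truth.

Edge perturbations are specified on the correlation scale (so a delta of
0.3 means that edge's correlation moves by 0.3), applied to the target
group's matrix and projected back to the PSD cone by eigenvalue clipping
at 1e−8 with variances restored.  The projection must land within half
the requested delta of the target or the perturbation is rejected as
infeasible.  Shifts that leave [−1, 1] are rejected outright.

What the generator does *not* emulate: site effects, non-Gaussian tails,
partial-volume artefacts, spatial autocorrelation beyond the factor
structure, and any coupling between MMSE and SUVR.  Passing recovery
tests therefore demonstrate that the pipeline detects the modelled class
of connectivity differences at the stated sizes — not that real cohorts
carry such differences.

### Recovery experiment design

The connectivity-recovery experiment disconnects 4 cerebellar lobules:
every edge incident to a target lobule loses 0.3 correlation in the
patient group, with group mean vectors equalized so the covariance change
is the only signal.  Detection is the ROI-wise comparison of nodal Z
strength (row sums of the individual Z matrix) with Bonferroni 0.05/26.
Two power facts drove this design, measured with the package's own
simulation oracle: a single perturbed edge moves a subject's Z on that
edge by only ≈ δ/(1 − r²) ≈ 0.5 SD (undetectable region-wise at
n = 150/group), and edges sharing a node are strongly correlated through
the subject's common deviation, so within-clique perturbations add less
power than their count suggests.  Disconnecting a lobule from the whole
network concentrates ~25 perturbed edges on each target ROI and yields
per-ROI sensitivity above 0.9 at n = 150/group.

## Statistics

Shapiro–Wilk at α = 0.05 per group gates the test choice; both groups
must pass for the t branch.  Covariate control (age, sex) is linear
residualization applied before the t branch only — the nonparametric
branch runs on raw values, since no adjustment mechanism is defined for
it.  The Mann–Whitney branch reports the Hodges–Lehmann shift estimate
with its distribution-free CI (normal-approximation rank cutoffs), so
differences and CIs are available regardless of branch.  Log
transformation (natural log; nonpositive features shifted by ε − min
with the shift recorded) is offered for non-normal metrics.  Bonferroni
is the governing multiple-comparison correction (0.05/26, 0.05/72); FDR
is deliberately not part of the reported pipeline.

## Classification

All data-dependent choices — standardization parameters, univariate
filtering, LASSO selection, hyperparameter tuning — are computed on the
train split only; tests assert that perturbing test rows or test labels
leaves every selection unchanged.  The univariate filter runs at
α = 0.05 uncorrected (it is a screening step, not an inference), then
L1-logistic LASSO with λ chosen by minimum 5-fold CV log-loss over a
25-point grid.  Default hyperparameter grids (SVM C ∈ {0.1, 1, 10} with
RBF/linear kernels; RF 100/500 trees; LR C ∈ {0.1, 1, 10}; one-hidden-
layer MLP of 16 or 64 units; boosted trees of depth 2–4; k-NN
k ∈ {3, 5, 7, 11}) are shipped defaults and fully overridable.  The best
family per task is chosen by CV AUC — never by test performance.  CIs
are stratified-bootstrap percentile intervals (2000 resamples by
default).  The later disease stage is always the positive class.

Shapley attribution uses permutation sampling against a train-median
baseline (optionally a k-row background).  Because each sampled ordering
telescopes from the baseline prediction to the subject's prediction, the
efficiency axiom holds exactly for the estimator; Monte-Carlo standard
errors are reported per cell, and a warning is raised when the sample
count is below twice the feature count.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] after `corrcoef` to absorb
  floating-point overshoot; zero-variance ROIs are an error naming the
  ROI.
* Pipeline-level problem sizes are configuration: the shipped example
  configs and the acceptance script run the metric stage without
  small-world normalization at the full 612-subject size (the rewiring
  ensemble dominates cost and is off by default there), and with
  n_random = 3–100 elsewhere as stated per run.
* The single global seed fans out to per-stage seeds through
  `SeedSequence.spawn` in fixed stage order, so stages are individually
  reproducible and re-running a config reproduces artifacts bit for bit.

## Known limitations

* The 72-ROI cortical composition is a reconstruction: the authoritative
  list is not public, so the default takes the AAL cerebral labels minus
  occipital-proper regions and deep grey nuclei (36 bilateral pairs),
  keeping Lingual with the occipitotemporal group; the selection rules
  are configurable and the compartment counts are enforced.
* Grid-AUC values are not comparable across different grids; the grid is
  recorded with every metric table.
* The perturbation Z network conflates mean and covariance atypicality
  (see above); group comparisons of network metrics between groups with
  different deposition levels partly reflect deposition level itself.
* Synthetic classification AUCs reflect the generator's effect sizes,
  not any real cohort's separability.
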