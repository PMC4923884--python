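# Methods

## Model and estimation

Expression profiles of P genes across N samples are treated as draws from a
multivariate normal N(μ, Σ). The gene network is the support of the precision
matrix Θ = Σ⁻¹: Θᵢⱼ = 0 iff genes i and j are conditionally independent given
all other genes. Θ is estimated by maximizing the penalized log-likelihood
log det Θ − tr(SΘ) − ρ‖Θ‖₁ with S the empirical covariance and ρ ≥ 0.

Numerical conventions, all exposed as flags:

- **Covariance normalization** is 1/N (the maximum-likelihood form that the
  penalized likelihood assumes); `ddof=1` switches to the unbiased 1/(N−1).
- **Standardization**: genes are centered and scaled to unit variance before
  estimation (default on), so a single ρ is comparable across genes and S is
  a correlation matrix. Zero-variance genes are left unscaled with a warning.
- **Diagonal penalty**: the default penalizes off-diagonal entries only, the
  dominant solver convention. The literal full-matrix penalty is available
  via `penalize_diagonal=True` and is solved exactly through the identity
  that, because Θᵢᵢ > 0 at any optimum, the diagonal part of the L1 term is
  the linear term ρ·tr(Θ), absorbable into S + ρI.
- **Solver**: `sklearn.covariance.graphical_lasso` backs the estimation (the
  inner lasso tolerance is tied to the outer tolerance; the default 1e-6 is
  far below the 1e-8 support threshold). ρ = 0 is a plain inverse and
  requires S invertible (condition number ≤ 1e12). Non-convergence is
  reported honestly via the `converged` flag; networks are never built from
  non-converged estimates. An independent monotone proximal-gradient solver
  (tests/_reference.py) cross-checks the optimum in the test suite; its
  objective trace is non-decreasing by construction, which is also the
  monotonicity property the tests assert (classical block-coordinate-descent
  implementations are not monotone in the primal objective).
- **Edge support**: |Θᵢⱼ| > 1e-8 (strict), OR-symmetrized over the triangles.

### Penalty selection

ρ is scanned over {0.0, 0.1, …, 1.0}. For each feasible value the network is
built and checked for the existence of at least one seed module set (see
below); the selected ρ is the smallest feasible value whose network admits
one — i.e. the densest network that is still partitionable. ρ = 0 is skipped
with a warning when P > N (singular S). Edge counts are expected to be
non-increasing in ρ; a violation is logged, not fatal. The scan checks seed
sets with min(k, #positive-degree nodes) hubs so that sparse grid points do
not abort the scan.

### Degree-distribution diagnostic

A least-squares fit of log10(frequency) against log10(degree) over degrees
≥ 1 reports slope and R². Slope < −0.5 with R² > 0.5 is labelled
"scale-free-like". This is a shape heuristic for sanity-checking, not a
formal power-law test, and it is purely diagnostic: nothing downstream
depends on it.

## Module partition

- **Hubs**: the k = 20 largest-degree genes, ties broken lexicographically
  (logged when the tie crosses the rank-k boundary). An initialized module is
  the hub plus its direct neighbors; the hub is a member of its own module
  (merged modules must contain their hubs).
- **Seed sets**: all *maximal* collections of ≥ 2 pairwise-disjoint
  initialized modules, computed as maximal cliques of the disjointness graph
  over the ≤ 20 modules. Maximality keeps redundant sub-collections from
  inflating the candidate list; `maximal=False` enumerates every disjoint
  collection for sensitivity analysis.
- **Merging**: the remaining modules are processed in descending hub degree
  (ties by hub id) — the order matters because targets update after every
  merge, and the degree-descending order is stable and consistent with the
  hub-centric design. Each module is absorbed by set-union into the current
  module with the largest overlap; overlap is raw intersection cardinality
  (Jaccard available behind a flag). Ties go to the target whose seed hub has
  the larger degree, then the smaller id. A module overlapping no target is
  still merged into the tie-break target by default (the merge rule applied
  literally at overlap 0); `orphan_policy="standalone"` starts a new module
  instead. Both paths are logged loudly.
- **Score**: E = mean pairwise intersection cardinality over the final
  modules. All partitions attaining the minimal E are returned (distinct
  seed sets can tie, and can even produce identical module sets — duplicates
  by module-set equality are dropped). All orderings are deterministic, so a
  run is byte-reproducible.

## Cohort handling

- Probesets mapping to one gene symbol collapse to the probeset with the
  maximal per-probeset summary across samples; the summary is the **mean**
  by default ("maximum value" needs a scalar per probeset, and the mean is
  the standard reading), with max and median as options. Ties break to the
  lexicographically smallest probeset id. Unmapped probesets are dropped.
- Risk groups: survival strictly greater than the cutoff (365 or 730 days)
  is low risk; otherwise high risk, except patients censored strictly before
  the cutoff, which are flagged `excluded` — retained with the flag for
  audit, never silently dropped. A subtype mode assigns low risk to a named
  subtype (e.g. proneural) instead.
- DEG filter: per-gene two-sided Student's t-test (pooled variance; Welch
  behind a flag), selection at p < α = 0.05 with *no* multiple-testing
  correction — the filter is dimension reduction before network estimation,
  not inference. Genes constant in both groups are flagged degenerate with
  p = 1.

## Evaluation harness

- **Clustering**: agglomerative clustering of patients (correlation
  distance, average linkage by default — the standard choice for expression
  heat maps; both are configurable), cut at two clusters. The cluster with
  the smaller median survival among observed deaths is labelled high risk
  (clusters without any deaths fall back to the median over all their
  survival times). Two-group log-rank test via lifelines.
- **Monte-Carlo null**: the module's log-rank p is compared against `reps`
  random gene sets of the same size drawn without replacement from the
  network genes (default 100), reporting all null p-values, their mean, and
  the fraction below the observed p.
- **SVM-RFE**: hand-written elimination loop (library RFE computes its step
  from the initial feature count; here each round removes 10% *of the
  remaining* features, floor 1, lowest |weight| of a linear SVM first, ties
  by gene id). Elimination stops when `n_features` (default 30) survive;
  survivors are returned ordered by final |weight|. Requesting all genes is
  the identity ranking.
- **Re-sampling classification** (default 100 iterations, fully seeded): per
  iteration the majority class is subsampled to 1:1 (balancing precedes the
  split), the cohort is split 4:1 stratified, SVM-RFE runs on the training
  split only, SVM hyperparameters are grid-searched by stratified 5-fold CV
  on the training split (linear and RBF kernels, C ∈ 2^(−5..15), γ ∈
  2^(−15..3) in steps of 2⁴ — a coarse lattice keeps 100× re-sampling
  tractable; the grid is a parameter), and the refit model is scored on the
  validation split. SEN = TP/(TP+FN), SPC = TN/(TN+FP), ACC = (TP+TN)/n,
  MCC = (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a metric with a zero
  denominator is reported as undefined, never as 0. Averages are arithmetic
  means over iterations where the metric is defined. libsvm iterations are
  capped at 20 000 — at huge C on non-separable data the solver can
  otherwise iterate almost indefinitely; the cap does not bind for
  well-posed fits.
- High-risk patients are the positive class throughout.
- All randomness flows from one master seed through
  `numpy.random.SeedSequence` spawning (one child per re-sampling
  iteration), so reports are bit-reproducible and iterations are
  independently reproducible from their recorded child seeds.

## Synthetic data generator

`make_model` builds a sparse, hub-dominated precision matrix: per planted
module a star of one hub and `hub_degree` leaves with off-diagonal weight
−w, plus optional random background edges (weight −0.25) among the leftover
genes; unit diagonal, with per-component diagonal loading up to a minimum
eigenvalue of 0.05. The default hub weight is w = 0.8/√(hub_degree): the
1/√degree scaling keeps each star block's minimum eigenvalue at a fixed
0.2 positive-definiteness margin regardless of degree, and the 0.8 scale
puts the implied edge partial correlations near 0.28 (at degree 8) — strong
but realistic co-expression that a penalty grid with step 0.1 can resolve.
A substantially smaller scale would push the implied marginal correlations
below the grid's smallest nonzero penalty, making every grid network empty
and the planted structure unrecoverable by construction rather than by
failure of the method.

`sample_expression` draws i.i.d. multivariate-normal samples blockwise over
the connected components of the precision support (so very large mostly-
diagonal models sample cheaply). Class 2 receives per-gene mean shifts on
the shifted modules' genes: signed (up or down with equal probability) and
scaled by Uniform(0.5, 1.5) times the overall effect size, in units of each
gene's marginal sd — disease modules dysregulate their members to different
extents and directions, and a uniform one-directional shift would be
invisible to correlation-distance clustering (it cancels when sample
profiles are centered). Survival is exponential per class with rates set so
that ~40% of short-survival (class 2) and ~10% of long-survival patients
experience the event within the two-year cutoff; censoring times are uniform
on (0, 10 years].

What the generator does *not* emulate: probe-level microarray noise,
RNA-seq count distributions (the model is Gaussian, matching the method's
own assumption), batch effects, and overlapping/nested modules. Passing
tests therefore demonstrate correctness of the algorithms under the model's
own assumptions, not robustness to real-data violations of them.

## Problem sizes

The test suite and the acceptance script run the recovery analyses at
30 genes / 2 000 samples, the DEG calibration at 10 000 genes / 200 samples,
and the re-sampling harness at 25 repetitions — sizes chosen so the full
pipeline, including grid-searched SVMs, remains a desk-scale computation
while leaving the statistical conclusions (support F1, module Jaccard, null
calibration bands) stable across seeds.

## Known limitations

- The merge result depends on the processing order of the remainder; the
  degree-descending order is a documented convention, not a theorem.
- The penalty scan selects the smallest feasible ρ, which admits the most
  spurious edges among feasible networks; stability-based selection (e.g.
  StARS) is out of scope.
- The log-rank comparison treats clustering output as fixed; no correction
  is made for having chosen the cluster boundary from the same data.
- With very small validation splits the per-iteration confusion matrices are
  coarse; averaged metrics remain informative but per-iteration metrics can
  be undefined (and are reported as such).
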