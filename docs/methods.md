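# Methods

## The estimation problem

Each subject contributes a BOLD signal matrix `X ∈ R^{T×N}` (T volumes,
N ROIs). Every column is z-scored to mean 0 and unit sample standard
deviation before any estimator runs; this makes the sparsity weight λ
comparable across subjects and estimators (the Pearson baseline is
scale-invariant anyway; for the regression-based estimators the choice
matters and is applied uniformly).

The regularized estimators minimize

```
f(X, W) + λ‖W‖₁(off-diagonal) + β·tr(WᵀLW)     s.t. diag(W) = 0
```

with two interchangeable data-fit terms:

* `regression` (default): `f = ‖X − XW‖_F²`. Column i of `W` regresses
  ROI i on all other ROIs, so the estimate carries partial-correlation
  structure. The problem is column-separable given `L`.
* `covariance`: `f = ½‖W − XᵀX‖_F²`, which shrinks the sample
  second-moment matrix directly. It is kept because the classical
  iterative update `W ← W − α(W − XᵀX + βLW)` implements exactly this
  variant.

The constraint `diag(W) = 0` removes trivial self-regression; it is
enforced by projection after every proximal step, and the diagonal is
excluded from the ℓ₁ penalty.

### The inter-similarity prior

The graph penalty encodes the assumption that similar ROIs have similar
connection profiles. The similarity graph `S` is the positive part of the
Pearson correlation matrix of `X` with a zero diagonal (negative
correlations carry no similarity information under this prior and are
clipped). With degree matrix `D_ii = Σ_j S_ij`,

* unnormalized Laplacian `L = D − S` gives the identity
  `tr(Wᵀ L W) = ½ Σ_ij S_ij ‖W_i,: − W_j,:‖²` (verified to 1e-10 in the
  test suite);
* normalized Laplacian `L = I − D^{-1/2} S D^{-1/2}` (the default) has
  spectrum in [0, 2] and equalizes the influence of high- and low-degree
  ROIs. A zero-degree node's `D^{-1/2}` entry is defined as 0, making its
  Laplacian row an identity row (the penalty simply shrinks that node's
  row of `W`).

The degree matrix is always built from the fixed similarity graph `S`,
never from the unknown `W` — otherwise the program would no longer be the
stated convex problem. A custom `S` can be injected through
`SolverConfig.similarity_override`.

## Solver

Proximal gradient descent (ISTA) from `W⁰ = 0`:

1. exact smooth gradient: `2Xᵀ(XW − X) + 2βLW` (regression) or
   `(W − XᵀX) + 2βLW` (covariance);
2. backtracking line search: candidate
   `W' = prox(W − αg, αλ)`, accepted when
   `g(W') ≤ g(W) + ⟨g, W'−W⟩ + ‖W'−W‖²/(2α)`, otherwise α is halved.
   The accepted step warm-starts the next iteration (doubled once,
   capped at the initial step `1/‖XᵀX‖₂`);
3. proximal operator: elementwise soft thresholding
   `sgn(v)·max(|v| − αλ, 0)`, then the diagonal is zeroed.

Note the threshold is `α·λ` (step-scaled), which is what makes the
iteration minimize the stated objective; a `unscaled_prox` switch
reproduces the historical update with an unscaled threshold and without
the gradient's constant factors for comparison, but that iteration solves
a differently-scaled problem and is not used anywhere else.

Accepted steps guarantee a non-increasing full objective (asserted on
every solver run in the suite with 1e-10 slack). Convergence is declared
when the relative objective change drops below `tol` (default 1e-6,
`max_iter` 1000); hitting the cap flags `converged=False` on the result
rather than raising. Because the stopping rule watches the objective, the
iterate can lag the objective plateau: reaching KKT residuals of ~1e-6
requires `tol≈1e-12` on small instances, which the oracle tests use. For
λ>0 the returned `W` contains exact zeros produced by the prox — no
epsilon thresholding is ever applied.

Two postprocessing steps are applied (in this order) before
featurization and topology metrics: symmetrization `(W + Wᵀ)/2` (the
regression form is not symmetric; the standard projection onto
symmetric matrices) and max-absolute normalization into [−1, 1]. The raw
asymmetric solution is retained on the `SolverResult`.

## Classification pipeline

Edge features are the strict upper triangle of the symmetric network
(6,670 features for N=116). The pipeline is deliberately minimal so that
performance differences are attributable to the network estimator:

* edge screening by two-sample pooled-variance t-test at a fixed
  threshold (default p < 0.01; Welch variant available). Edges with zero
  variance in both groups get p = 1. Screening is fitted on training
  folds only;
* selected features are z-scored across the training subjects (transform
  reused on the test subject). A soft-margin SVM at fixed C is
  scale-sensitive, and raw edge weights vary between subjects on an
  arbitrary, estimator-dependent scale; without this step the classifier
  can collapse into a majority-class voter, which in leave-one-out
  cross-validation with balanced groups systematically predicts the
  *wrong* class;
* linear SVM with C = 1;
* outer leave-one-out cross-validation; per outer fold an inner CV
  (inner-LOO by default, k-fold optional for speed) grid-searches the
  estimator hyperparameters — λ, β over powers of two in [2⁻⁵, 2⁵], or
  11 proportional-threshold levels {1%, 10%, …, 100%} for the Pearson
  baseline. Accuracy ties are broken toward the sparsest model (largest
  λ, then largest β, or smallest keep-fraction).

Connectivity estimation is by far the expensive stage, so edge features
are computed once per (subject, grid point) and cached before the CV
loops; this is leakage-free because each subject's network depends only
on that subject's data. If screening selects nothing, the fold falls back
to predicting the training-majority class and is flagged in the report.

Reported metrics: accuracy, sensitivity and specificity as percentages
(2 decimals) recomputed exactly from the confusion counts, and the
rank-based (Mann–Whitney) AUC of the decision scores with ties counted
half. Metrics with zero denominators are reported as undefined, never 0.
A non-nested variant (`loo_accuracy`) evaluates one fixed hyperparameter
setting by plain LOO; maximizing it over a grid is optimistically biased
and the docstring says so.

**Consensus connections** are the edges selected in *every* outer fold,
reported with group-mean weights and full-sample t-test p-values, sorted
by p.

## Topology metrics

Metrics operate on the positive weights (distance and triangle formulas
are undefined for negative weights; negatives are set to 0). `weighted`
mode keeps the weights — distances are reciprocal weights, clustering is
the Onnela geometric-mean triangle form; `binary` mode first keeps the
strongest fraction of edges (proportional threshold) and sets them to 1.

* Cp: mean nodal clustering (nodes with degree < 2 contribute 0);
* Lp: mean shortest-path distance over connected pairs; disconnected
  pairs are excluded and counted;
* E_global: mean inverse distance over ordered pairs (0 when apart);
* Q: Newman modularity of the deterministic greedy
  (Clauset–Newman–Moore) partition. Canonical Q lies in [−½, 1]; any
  source reporting Q well above 1 is using a different scaling, which
  this package does not reproduce;
* small-world: γ = Cp/⟨Cp_rand⟩, λ = Lp/⟨Lp_rand⟩, σ = γ/λ against an
  ensemble of degree-preserving double-edge-swap nulls (default 100
  networks, 10·|E| swap attempts each, seeded). Weighted nulls rewire
  the binary topology and permute the original weight multiset onto the
  new edges — exact degree preservation, approximate strength
  preservation;
* hubs: top-k nodes (default k=10) by degree/strength, or nodes above
  mean + 1 sd.

## Synthetic cohorts

The generator realizes the modeling assumption the estimator exploits,
so that recovery is a meaningful end-to-end test:

* **ground truth**: a block-modular sparse precision matrix. Nodes are
  split into contiguous modules; within-module pairs receive a negative
  precision entry (magnitude `within_strength`, ±25% jitter) with
  probability `within_density` (default 0.6), plus rare weak
  cross-module edges (density 0.02). Negative precision entries imply
  positive partial correlations, which survive the positive-PC
  similarity graph. The diagonal is loaded (increment 0.05 per attempt,
  max 100) until the smallest eigenvalue reaches 0.1, guaranteeing SPD.
  Same-module nodes connect to largely the same partners, so similar
  nodes have similar rows — inter-similarity by construction;
* **signals**: rows i.i.d. `N(0, P⁻¹)`, optional AR(1) temporal
  smoothing and white observation noise, then column standardization.
  Rows are i.i.d. by default because every estimator consumes only
  second-order structure and i.i.d. sampling admits closed-form oracles
  (the partial correlation of the truth is `−P_ij/√(P_ii·P_jj)`,
  verified empirically at T=5000 to within 0.05);
* **two-group cohorts**: group B strengthens `n_planted` within-module
  precision entries by `effect_size` (both groups re-loaded to SPD);
  per-subject truths get ±5% multiplicative off-diagonal jitter. The
  default study conditions are 20 ROIs in 4 modules, 150 volumes,
  30 subjects per group, 3 planted edges at effect size 0.4.

What the generator does *not* emulate: hemodynamic response convolution,
scanner noise spectra, head-motion artifacts, spatial autocorrelation of
real parcellations, or between-site heterogeneity. Passing recovery
tests therefore demonstrates correctness of the estimation and testing
machinery under the model's own assumptions — not performance on real
rs-fMRI, which additionally depends on preprocessing quality and on how
well the inter-similarity assumption holds in vivo.

## Numerical choices and edge cases

* Proportional thresholding keeps `round(f·N(N−1)/2)` edges; ties broken
  deterministically by (|w| descending, row, column) so results are
  platform-independent.
* Constant ROI columns are an error naming the offending column index
  (they cannot be standardized or correlated).
* All-zero matrices pass through weight normalization unchanged.
* Line-search step underflow below 1e-15 aborts the solve with the
  reason recorded on the result.
* Every stochastic routine takes an explicit seed; identical seeds give
  bit-identical cohorts, ensembles and reports.

## Known limitations

* The solver is plain ISTA; FISTA acceleration and ADMM are out of
  scope. At the intended scale (N ≈ 116, T ≈ 130) a solve converges in
  well under a second, so acceleration is unnecessary.
* Inner-LOO grid search is O(n²·|grid|) SVM fits per report; for large
  synthetic cohorts the k-fold inner CV option trades a little
  selection stability for speed.
* Weighted small-world nulls preserve strength only approximately;
  strength-preserving rewiring is not implemented.
* The leave-one-out protocol itself has high variance at small n, and
  on null data interacts with class imbalance (the training majority
  always opposes the held-out subject); the feature z-scoring step
  neutralizes the degenerate form of this effect but cannot remove the
  protocol's variance.
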