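# sgrnet

Sparse + graph-regularized estimation of functional connectivity networks
(FCNs) from ROI-wise BOLD time series, with the downstream machinery used
in resting-state fMRI group studies: edge-feature classification under
nested leave-one-out cross-validation, consensus-connection extraction,
and graph-theory characterization (small-world indices, efficiency,
modularity, hubs).

The package is aimed at researchers who work with already-parcellated
resting-state fMRI (one `T x N` matrix per subject, e.g. 116 AAL regions)
and want partial-correlation networks that are both **sparse** and
**structured**: the estimator assumes that similar regions share similar
connection patterns and encodes that assumption as a graph penalty.

## The model

For a subject's standardized BOLD matrix `X ∈ R^{T×N}` (T volumes, N
ROIs), the network `W ∈ R^{N×N}` is the solution of the convex program

```
min_W  ‖X − XW‖_F²  +  λ‖W‖₁  +  β·tr(WᵀLW)      s.t.  W_ii = 0
```

* the data-fit term regresses each ROI on all others, so `W` carries
  partial-correlation (conditional dependence) structure rather than full
  correlation;
* the `ℓ₁` term drives spurious edges to exactly zero (λ ≥ 0);
* the graph term is the inter-similarity prior: with `L` the normalized
  Laplacian of a nonnegative ROI-similarity graph `S` (here the positive
  part of the Pearson correlation matrix),
  `tr(Wᵀ(D−S)W) = ½·Σ_ij S_ij·‖W_i,: − W_j,:‖²`, so similar ROIs are
  pulled toward similar rows of `W` (β ≥ 0).

Setting λ>0, β=0 gives the classical sparse-representation (SR)
estimator, λ=0, β>0 the purely graph-regularized (GR) one, and both
positive the combined SGR estimator; Pearson correlation with optional
proportional thresholding is included as the baseline. The program is
solved by proximal gradient descent (ISTA): a line-searched gradient step
on the smooth terms followed by soft thresholding and projection onto the
zero-diagonal constraint. A `covariance` data-fit variant
`½‖W − XᵀX‖_F²` is available as well.

## Worked example

`examples/estimate_networks.py` simulates one subject (150 volumes, 20
ROIs) from a modular Gaussian ground truth and estimates all four network
types:

```
  PC: 190/190 edges nonzero, precision 0.14, recall 1.00 vs true support
  SR:  83/190 edges nonzero, precision 0.30, recall 0.96 vs true support
  GR: 190/190 edges nonzero, precision 0.14, recall 1.00 vs true support
 SGR:  83/190 edges nonzero, precision 0.30, recall 0.96 vs true support
```

Correlation-based and purely graph-regularized networks are dense — every
one of the 190 possible edges is nonzero, so precision against the true
support is at the 14% base rate. The ℓ₁ penalty (λ=20 here) removes more
than half of the edges while keeping 96% of the true ones.

`examples/classify_cohort.py` runs the full two-group pipeline on a
synthetic cohort (15+15 subjects, 3 planted discriminative edges):

```
accuracy    100.0%
sensitivity 100.0%
specificity 100.0%
AUC         1.0000
most chosen hyperparameters: sgr(lam=2,beta=8)
```

followed by the consensus-connection table — the edges that pass the
two-sample t-test (p < 0.01) in *every* outer cross-validation fold, with
group-mean weights and full-sample p-values (`planted edges in
consensus: 2 of 3` at this cohort size; the acceptance-scale cohort of 30
per group recovers all three). Additional rows are edges whose weights
shift as a side effect of the planted precision change.

`examples/topology_metrics.py` prints the graph-theory bundle of an
estimated network against 100 degree-preserving rewired nulls:

```
clustering coefficient Cp   0.1879
characteristic path Lp      2.1126
global efficiency           0.5490
modularity Q                0.3413
gamma (Cp/Cp_rand)          1.0903
lambda (Lp/Lp_rand)         1.0304
sigma (gamma/lambda)        1.0581
```

σ = γ/λ > 1 marks small-world organization: more clustered than
degree-matched random networks at comparable path length.

## Command line

The same workflows are scriptable from a shell (see
`examples/simulate_and_cli.py`):

```
sgrnet simulate --out cohort/ --n-per-group 10 --n-rois 20 --seed 3
sgrnet estimate --manifest cohort/manifest.tsv --out fcn/ \
    --method sgr --lambda 2 --beta 32
sgrnet classify --manifest cohort/manifest.tsv --out report/
sgrnet metrics --fcn fcn/NC_001_fcn.tsv --out topo.json
```

Inputs and outputs are plain TSV/CSV/JSON; all randomness flows from
`--seed`.

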