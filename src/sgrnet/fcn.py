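"""Functional connectivity network (FCN) estimation.

Four estimation schemes are provided for an ROI-wise BOLD matrix
``X in R^{T x N}`` (columns standardized):

* **PC** — Pearson correlation, ``W_ij = corr(x_i, x_j)``, optionally
  sparsified by keeping the strongest fraction of edges.
* **SR** — sparse representation: the l1-penalized partial-correlation
  program ``min_W ||X - XW||_F^2 + lam*||W||_1`` s.t. ``W_ii = 0``.
* **GR** — graph-regularized: the inter-similarity penalty
  ``beta * tr(W^T L W)`` alone, where L is the (normalized) Laplacian of the
  positive-PC similarity graph between ROIs.
* **SGR** — both penalties combined.

The inter-similarity prior states that similar ROIs should have similar
rows of W; with the combinatorial Laplacian ``L = D - S`` this is exactly
``tr(W^T L W) = 1/2 * sum_ij S_ij * ||W_i,: - W_j,:||^2``.
"""

from __future__ import annotations

import numpy as np

from .types import (
    BoldTimeSeries,
    ConnectivityMatrix,
    GraphLaplacian,
    InvariantError,
    SimilarityGraph,
)

__all__ = [
    "standardize",
    "pearson_fcn",
    "threshold_by_sparsity",
    "build_similarity",
    "build_laplacian",
    "graph_penalty",
    "sgr_objective",
    "estimate",
    "symmetrize",
    "normalize_weights",
]


def _check_no_constant_columns(x: np.ndarray) -> None:
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise InvariantError(
            f"constant ROI column(s) at index {bad.tolist()}: cannot standardize/correlate"
        )


def standardize(ts: BoldTimeSeries) -> BoldTimeSeries:
    """Z-score each ROI column to mean 0 and unit sample (ddof=1) sd."""
    x = ts.data
    _check_no_constant_columns(x)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    return BoldTimeSeries(data=z, subject_id=ts.subject_id, roi_labels=list(ts.roi_labels))


def pearson_fcn(ts: BoldTimeSeries) -> ConnectivityMatrix:
    """Full-correlation FCN: W_ij is the Pearson correlation of columns i, j."""
    _check_no_constant_columns(ts.data)
    w = np.corrcoef(ts.data, rowvar=False)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix(weights=w, roi_labels=list(ts.roi_labels), estimator_tag="PC")


def threshold_by_sparsity(w: ConnectivityMatrix, keep_fraction: float) -> ConnectivityMatrix:
    """Keep the strongest ``keep_fraction`` of off-diagonal edges by |weight|.

    The kept edge count is ``round(keep_fraction * N(N-1)/2)``.  Ties are
    broken deterministically by (|w| descending, row index, column index).
    The diagonal is untouched.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if not w.is_symmetric(tol=1e-8):
        raise InvariantError("threshold_by_sparsity requires a symmetric matrix")
    if keep_fraction == 1.0:
        return w.with_weights(w.weights.copy(), tag="PC_thresholded")
    n = w.n_rois
    iu, ju = np.triu_indices(n, k=1)
    mags = np.abs(w.weights[iu, ju])
    n_keep = int(round(keep_fraction * iu.size))
    order = np.lexsort((ju, iu, -mags))  # |w| desc, then row, then col
    keep = order[:n_keep]
    out = np.zeros_like(w.weights)
    np.fill_diagonal(out, np.diag(w.weights))
    out[iu[keep], ju[keep]] = w.weights[iu[keep], ju[keep]]
    out[ju[keep], iu[keep]] = w.weights[ju[keep], iu[keep]]
    return w.with_weights(out, tag="PC_thresholded")


def build_similarity(ts: BoldTimeSeries) -> SimilarityGraph:
    """Inter-ROI similarity: positive part of the Pearson FCN, zero diagonal."""
    pc = pearson_fcn(ts).weights
    s = np.maximum(pc, 0.0)
    np.fill_diagonal(s, 0.0)
    return SimilarityGraph(s=s)


def build_laplacian(s: SimilarityGraph, normalized: bool = True) -> GraphLaplacian:
    """Laplacian of the similarity graph.

    normalized: ``L = I - D^{-1/2} S D^{-1/2}`` with ``D_ii = sum_j S_ij``;
    a zero-degree node's ``D^{-1/2}`` entry is 0, so its row of L is the
    identity row.  Unnormalized: ``L = D - S``.  Both are symmetric PSD.
    """
    d = s.s.sum(axis=1)
    if normalized:
        with np.errstate(divide="ignore"):
            dinv = np.where(d > 0, 1.0 / np.sqrt(d), 0.0)
        lap = np.eye(s.n_rois) - dinv[:, None] * s.s * dinv[None, :]
    else:
        lap = np.diag(d) - s.s
    lap = (lap + lap.T) / 2.0
    return GraphLaplacian(l=lap, normalized=normalized)


def graph_penalty(w: ConnectivityMatrix | np.ndarray, lap: GraphLaplacian) -> float:
    """Inter-similarity penalty tr(W^T L W)."""
    wm = w.weights if isinstance(w, ConnectivityMatrix) else np.asarray(w, dtype=float)
    if wm.shape[0] != lap.n_rois:
        raise InvariantError(
            f"shape mismatch: W has {wm.shape[0]} rows, L is {lap.n_rois}x{lap.n_rois}"
        )
    return float(np.trace(wm.T @ lap.l @ wm))


def sgr_objective(
    ts: BoldTimeSeries,
    w: ConnectivityMatrix | np.ndarray,
    lam: float,
    beta: float,
    lap: GraphLaplacian,
    variant: str = "regression",
) -> float:
    """Full SGR objective: data fit + lam*||W||_1(off-diag) + beta*tr(W^T L W).

    variant="regression": data fit ||X - XW||_F^2 (partial-correlation form);
    variant="covariance": data fit 0.5*||W - X^T X||_F^2.
    The diagonal is excluded from the l1 term (it is constrained to zero).
    """
    if lam < 0 or beta < 0:
        raise ValueError("hyperparameters lam and beta must be nonnegative")
    from .solver import smooth_objective  # local to avoid import cycle

    wm = w.weights if isinstance(w, ConnectivityMatrix) else np.asarray(w, dtype=float)
    off = wm - np.diag(np.diag(wm))
    return smooth_objective(ts.data, wm, lap, beta, variant) + lam * float(
        np.abs(off).sum()
    )


def estimate(ts: BoldTimeSeries, config=None, **kwargs):
    """Estimate a regularized partial-correlation FCN.

    Dispatches on the hyperparameters in ``config`` (a
    :class:`~sgrnet.solver.SolverConfig`): ``lam>0, beta=0`` gives SR,
    ``lam=0, beta>0`` GR, both positive SGR, both zero an unpenalized
    per-column regression.  The similarity graph and Laplacian are built
    from ``ts`` (positive-PC) unless ``config.similarity_override`` is set.
    Returns a :class:`~sgrnet.solver.SolverResult` whose ``w`` has an exact
    zero diagonal.
    """
    from .solver import SolverConfig, solve

    if config is None:
        config = SolverConfig(**kwargs)
    return solve(ts, config)


def symmetrize(w: ConnectivityMatrix) -> ConnectivityMatrix:
    """Project onto symmetric matrices: (W + W^T)/2."""
    return w.with_weights((w.weights + w.weights.T) / 2.0)


def normalize_weights(w: ConnectivityMatrix) -> ConnectivityMatrix:
    """Scale W so the largest |entry| is 1; all-zero input is returned as is."""
    m = np.max(np.abs(w.weights))
    if m == 0:
        return w.with_weights(w.weights.copy())
    return w.with_weights(w.weights / m)
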