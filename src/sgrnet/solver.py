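"""Proximal gradient solver for the SR/GR/SGR convex programs.

The objective is split into a smooth part (data fit plus the graph
penalty ``beta * tr(W^T L W)``) and the nonsmooth l1 term, minimized by
ISTA-style iterations: a gradient step on the smooth part, then the
soft-thresholding proximal operator of ``step * lam * ||.||_1``, then
projection onto the constraint ``diag(W) = 0``.  The step size is chosen
by backtracking line search against the quadratic majorization
``g(W') <= g(W) + <grad, W'-W> + ||W'-W||_F^2 / (2*step)``, warm-started
from the previous iteration (doubled once per outer iteration, capped at
the initial step).

``unscaled_prox=True`` switches to a historical update rule found in some
toolboxes (gradient without its exact constant factors, l1 threshold not
scaled by the step size, fixed step, no line search); it is kept for
comparison only — it does not minimize the stated objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcn import build_laplacian, build_similarity, standardize
from .types import BoldTimeSeries, ConnectivityMatrix, GraphLaplacian, SimilarityGraph

__all__ = [
    "SolverConfig",
    "SolverResult",
    "soft_threshold",
    "smooth_objective",
    "smooth_gradient",
    "prox_step",
    "line_search",
    "solve",
]

_STEP_UNDERFLOW = 1e-15


@dataclass
class SolverConfig:
    """Hyperparameters and numerical settings for :func:`solve`.

    lam : l1 weight (lambda); 0 disables the sparsity penalty.
    beta : graph-regularizer weight; 0 disables the inter-similarity penalty.
    variant : "regression" for the partial-correlation fit ||X - XW||_F^2,
        "covariance" for 0.5*||W - X^T X||_F^2.
    """

    lam: float = 0.0
    beta: float = 0.0
    variant: str = "regression"
    normalized_laplacian: bool = True
    max_iter: int = 1000
    tol: float = 1e-6
    initial_step: float | None = None
    similarity_override: SimilarityGraph | None = None
    unscaled_prox: bool = False

    def __post_init__(self) -> None:
        if self.lam < 0 or self.beta < 0:
            raise ValueError("lam and beta must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.variant not in ("regression", "covariance"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.initial_step is not None and self.initial_step <= 0:
            raise ValueError("initial_step must be positive")


@dataclass
class SolverResult:
    w: ConnectivityMatrix
    objective_trace: list[float]
    n_iter: int
    converged: bool
    final_step: float
    message: str = ""
    raw_w: np.ndarray | None = None
    laplacian: GraphLaplacian | None = None
    config: SolverConfig | None = None


def soft_threshold(m: np.ndarray, theta: float) -> np.ndarray:
    """Elementwise l1 proximal operator sgn(m) * max(|m| - theta, 0)."""
    if theta < 0:
        raise ValueError(f"threshold must be nonnegative, got {theta}")
    return np.sign(m) * np.maximum(np.abs(m) - theta, 0.0)


def smooth_objective(
    x: np.ndarray,
    w: np.ndarray,
    lap: GraphLaplacian | None,
    beta: float,
    variant: str,
) -> float:
    """Smooth part of the objective: data fit + beta * tr(W^T L W)."""
    if variant == "regression":
        r = x - x @ w
        val = float(np.sum(r * r))
    elif variant == "covariance":
        r = w - x.T @ x
        val = 0.5 * float(np.sum(r * r))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if beta > 0:
        if lap is None:
            raise ValueError("beta > 0 requires a Laplacian")
        val += beta * float(np.trace(w.T @ lap.l @ w))
    return val


def smooth_gradient(
    ts: BoldTimeSeries | np.ndarray,
    w: np.ndarray,
    lap: GraphLaplacian | None,
    beta: float,
    variant: str = "regression",
) -> np.ndarray:
    """Exact gradient of the smooth part.

    regression: 2 X^T (XW - X) + 2*beta*L W
    covariance: (W - X^T X) + 2*beta*L W
    """
    x = ts.data if isinstance(ts, BoldTimeSeries) else np.asarray(ts, dtype=float)
    if w.shape[0] != x.shape[1]:
        raise ValueError(
            f"shape mismatch: X has {x.shape[1]} ROIs but W has {w.shape[0]} rows"
        )
    if variant == "regression":
        g = 2.0 * (x.T @ (x @ w - x))
    else:
        g = w - x.T @ x
    if beta > 0:
        g = g + 2.0 * beta * (lap.l @ w)
    return g


def prox_step(w: np.ndarray, grad: np.ndarray, step: float, lam: float) -> np.ndarray:
    """Gradient step, l1 shrinkage with threshold step*lam, zero diagonal."""
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    out = soft_threshold(w - step * grad, step * lam)
    np.fill_diagonal(out, 0.0)
    return out


class StepUnderflowError(RuntimeError):
    pass


def line_search(
    ts: BoldTimeSeries | np.ndarray,
    w: np.ndarray,
    grad: np.ndarray,
    step0: float,
    lam: float,
    beta: float,
    lap: GraphLaplacian | None,
    variant: str = "regression",
) -> tuple[float, np.ndarray]:
    """Backtracking: halve the step until the majorization condition holds.

    Accepts the first candidate W' = prox(W - step*grad, step*lam) with
    g(W') <= g(W) + <grad, W'-W> + ||W'-W||_F^2 / (2*step).
    """
    if step0 <= 0:
        raise ValueError("step0 must be positive")
    x = ts.data if isinstance(ts, BoldTimeSeries) else np.asarray(ts, dtype=float)
    g_w = smooth_objective(x, w, lap, beta, variant)
    step = step0
    while True:
        w_new = prox_step(w, grad, step, lam)
        delta = w_new - w
        quad = g_w + float(np.sum(grad * delta)) + float(np.sum(delta * delta)) / (
            2.0 * step
        )
        if smooth_objective(x, w_new, lap, beta, variant) <= quad + 1e-12:
            return step, w_new
        step /= 2.0
        if step < _STEP_UNDERFLOW:
            raise StepUnderflowError(
                f"line search step underflowed below {_STEP_UNDERFLOW:g}"
            )


def _default_step(x: np.ndarray) -> float:
    gram_norm = float(np.linalg.norm(x.T @ x, 2))
    return 1.0 / max(gram_norm, 1e-12)


def solve(
    ts: BoldTimeSeries,
    config: SolverConfig,
    w0: np.ndarray | None = None,
) -> SolverResult:
    """Run proximal gradient descent from W = 0 (or ``w0``) to convergence.

    Stops when the relative objective change drops below ``config.tol`` or
    after ``config.max_iter`` iterations (then ``converged=False``).  The
    returned trace is the full objective at every accepted iterate and is
    non-increasing; the diagonal of the solution is exactly zero, and for
    lam > 0 the off-diagonal zeros are exact (produced by the prox).
    """
    if not ts.is_standardized():
        ts = standardize(ts)
    x = ts.data
    n = ts.n_rois

    lap: GraphLaplacian | None = None
    if config.beta > 0 or config.similarity_override is not None:
        sim = config.similarity_override
        if sim is None:
            sim = build_similarity(ts)
        lap = build_laplacian(sim, normalized=config.normalized_laplacian)

    w = np.zeros((n, n)) if w0 is None else np.array(w0, dtype=float, copy=True)
    np.fill_diagonal(w, 0.0)

    def full_obj(wm: np.ndarray) -> float:
        off = wm - np.diag(np.diag(wm))
        return smooth_objective(x, wm, lap, config.beta, config.variant) + config.lam * float(
            np.abs(off).sum()
        )

    step0 = config.initial_step if config.initial_step is not None else _default_step(x)
    step = step0
    trace = [full_obj(w)]
    converged = False
    message = ""
    n_iter = 0

    for n_iter in range(1, config.max_iter + 1):
        grad = smooth_gradient(x, w, lap, config.beta, config.variant)
        if config.unscaled_prox:
            w_new = soft_threshold(w - step * grad, config.lam)
            np.fill_diagonal(w_new, 0.0)
        else:
            try:
                step, w_new = line_search(
                    x, w, grad, min(step * 2.0, step0), config.lam, config.beta,
                    lap, config.variant,
                )
            except StepUnderflowError as exc:
                message = str(exc)
                break
        obj = full_obj(w_new)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"objective became non-finite at iteration {n_iter}"
            )
        prev = trace[-1]
        trace.append(obj)
        w = w_new
        if abs(prev - obj) <= config.tol * max(abs(prev), 1e-12):
            converged = True
            break

    tag = {
        (True, True): "SGR",
        (True, False): "SR",
        (False, True): "GR",
        (False, False): "OLS",
    }[(config.lam > 0, config.beta > 0)]
    cm = ConnectivityMatrix(
        weights=w, roi_labels=list(ts.roi_labels), estimator_tag=tag
    )
    return SolverResult(
        w=cm,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
        final_step=step,
        message=message,
        raw_w=w.copy(),
        laplacian=lap,
        config=config,
    )
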