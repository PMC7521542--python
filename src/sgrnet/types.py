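"""Core containers for BOLD time series, connectivity matrices and graph priors.

The estimators in :mod:`sgrnet.fcn` consume a subject's ROI-wise BOLD signal
matrix ``X`` (T volumes x N ROIs) and produce an N x N edge-weight matrix
``W``.  The inter-similarity prior is carried by a nonnegative similarity
graph ``S`` between ROIs and its (normalized) graph Laplacian ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvariantError(ValueError):
    """Raised when a container's structural invariant is violated."""


def _as_float_matrix(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise InvariantError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise InvariantError(f"{name} contains non-finite entries")
    return arr


@dataclass
class BoldTimeSeries:
    """One subject's T x N ROI signal matrix (rows = volumes, columns = ROIs)."""

    data: np.ndarray
    subject_id: str = "subject"
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = _as_float_matrix(self.data, "BoldTimeSeries.data")
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise InvariantError(
                f"need at least 2 volumes and 2 ROIs, got T={t}, N={n}"
            )
        if self.roi_labels is None:
            self.roi_labels = [f"ROI_{i + 1}" for i in range(n)]
        elif len(self.roi_labels) != n:
            raise InvariantError(
                f"{len(self.roi_labels)} ROI labels for {n} columns"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def is_standardized(self, tol: float = 1e-10) -> bool:
        m = self.data.mean(axis=0)
        s = self.data.std(axis=0, ddof=1)
        return bool(np.all(np.abs(m) < tol) and np.all(np.abs(s - 1.0) < tol))


@dataclass
class ConnectivityMatrix:
    """N x N edge-weight matrix W with ROI labels and an estimator tag."""

    weights: np.ndarray
    roi_labels: list[str] | None = None
    estimator_tag: str = "PC"

    def __post_init__(self) -> None:
        self.weights = _as_float_matrix(self.weights, "ConnectivityMatrix.weights")
        n, m = self.weights.shape
        if n != m:
            raise InvariantError(f"weights must be square, got {n}x{m}")
        if self.roi_labels is None:
            self.roi_labels = [f"ROI_{i + 1}" for i in range(n)]
        elif len(self.roi_labels) != n:
            raise InvariantError(
                f"{len(self.roi_labels)} ROI labels for {n} nodes"
            )

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]

    def is_symmetric(self, tol: float = 1e-12) -> bool:
        return bool(np.max(np.abs(self.weights - self.weights.T)) <= tol)

    def with_weights(self, weights: np.ndarray, tag: str | None = None) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            weights=weights,
            roi_labels=list(self.roi_labels),
            estimator_tag=self.estimator_tag if tag is None else tag,
        )


@dataclass
class SimilarityGraph:
    """Nonnegative, symmetric inter-ROI similarity matrix S (zero diagonal)."""

    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = _as_float_matrix(self.s, "SimilarityGraph.s")
        n, m = self.s.shape
        if n != m:
            raise InvariantError(f"similarity must be square, got {n}x{m}")
        if np.max(np.abs(self.s - self.s.T)) > 1e-10:
            raise InvariantError("similarity matrix must be symmetric")
        if np.any(self.s < 0):
            raise InvariantError("similarity entries must be nonnegative")
        if np.any(np.abs(np.diag(self.s)) > 1e-12):
            raise InvariantError("similarity diagonal must be zero")

    @property
    def n_rois(self) -> int:
        return self.s.shape[0]


@dataclass
class GraphLaplacian:
    """Graph Laplacian L of a similarity graph; normalized or combinatorial."""

    l: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        self.l = _as_float_matrix(self.l, "GraphLaplacian.l")
        n, m = self.l.shape
        if n != m:
            raise InvariantError(f"Laplacian must be square, got {n}x{m}")

    @property
    def n_rois(self) -> int:
        return self.l.shape[0]


@dataclass
class GroundTruthNetwork:
    """Ground-truth conditional-dependence structure used by the simulator.

    ``precision`` is a symmetric positive-definite matrix; ``support`` marks
    its nonzero off-diagonal entries (the true edges); ``module_assignment``
    records which module each node belongs to.
    """

    precision: np.ndarray
    support: np.ndarray
    module_assignment: np.ndarray

    def __post_init__(self) -> None:
        self.precision = _as_float_matrix(self.precision, "precision")
        self.support = np.asarray(self.support, dtype=bool)
        self.module_assignment = np.asarray(self.module_assignment, dtype=int)
        n = self.precision.shape[0]
        if self.precision.shape != (n, n) or self.support.shape != (n, n):
            raise InvariantError("precision and support must be square and conformable")
        if np.max(np.abs(self.precision - self.precision.T)) > 1e-10:
            raise InvariantError("precision must be symmetric")
        w = np.linalg.eigvalsh(self.precision)
        if w.min() <= 0:
            raise InvariantError(f"precision must be SPD, min eigenvalue {w.min():g}")

    @property
    def n_rois(self) -> int:
        return self.precision.shape[0]

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


@dataclass
class SyntheticCohort:
    """A two-group synthetic cohort with known per-group ground truth."""

    subjects: list[BoldTimeSeries]
    labels: np.ndarray
    truth_a: GroundTruthNetwork
    truth_b: GroundTruthNetwork
    planted_edges: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.subjects) != len(self.labels):
            raise InvariantError("one label per subject required")
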