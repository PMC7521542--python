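"""MCI-vs-control classification from estimated connectivity networks.

Pipeline (kept deliberately simple so that differences in performance are
attributable to the network estimator, not the classifier): the strict
upper triangle of each subject's symmetric N x N connectivity matrix is the
feature vector (N(N-1)/2 edges); edges are screened by a two-sample t-test
at a fixed p threshold fitted on training data only; a linear soft-margin
SVM with C = 1 does the classification; performance is assessed by nested
leave-one-out cross-validation, with an inner cross-validation on each
training set doing grid search over the estimator hyperparameters.

Edge features for every (subject, grid point) pair are estimated once and
cached before the cross-validation loops; only the t-test screening and the
SVM are refitted per fold, which is what leakage control requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from . import fcn
from .solver import SolverConfig, solve
from .types import BoldTimeSeries, ConnectivityMatrix, InvariantError

__all__ = [
    "EdgeFeatureVector",
    "ConfusionCounts",
    "ClassificationReport",
    "GridPoint",
    "sgr_grid",
    "pc_threshold_grid",
    "vectorize_upper",
    "upper_index_map",
    "ttest_select",
    "train_svm",
    "decision_scores",
    "compute_metrics",
    "compute_auc",
    "cohort_features",
    "nested_loocv",
    "loo_accuracy",
    "consensus_connections",
]


# ---------------------------------------------------------------------------
# feature extraction


def upper_index_map(n: int) -> list[tuple[int, int]]:
    """Strict upper-triangle (i, j) pairs, i < j, in row-major order."""
    iu, ju = np.triu_indices(n, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


@dataclass
class EdgeFeatureVector:
    values: np.ndarray
    index_map: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.index_map):
            raise InvariantError("feature vector and index map lengths differ")


def vectorize_upper(w: ConnectivityMatrix) -> EdgeFeatureVector:
    """Flatten the strict upper triangle of a symmetric W (row-major).

    For N = 116 ROIs this yields 6,670 edge features.
    """
    if not w.is_symmetric(tol=1e-8):
        raise InvariantError("vectorize_upper requires a symmetric matrix")
    n = w.n_rois
    iu, ju = np.triu_indices(n, k=1)
    return EdgeFeatureVector(values=w.weights[iu, ju], index_map=upper_index_map(n))


# ---------------------------------------------------------------------------
# feature selection and classifier


def ttest_select(
    features: np.ndarray,
    labels: np.ndarray,
    p_threshold: float,
    welch: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t-test per edge; select edges with p < p_threshold.

    Pooled-variance Student's t by default (``welch=True`` for unequal
    variances).  An edge with zero variance in both groups carries no
    information; its p-value is set to 1.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    a = features[labels == classes[0]]
    b = features[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 subjects for a t-test")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant edges trigger scipy's precision-loss warning; their
        # p-values are overwritten with 1 below, so the warning is moot
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    p = np.where(np.isfinite(p), p, 1.0)
    return p < p_threshold, p


class _MajorityModel:
    """Fallback when t-test screening leaves no features."""

    def __init__(self, labels: np.ndarray):
        vals, counts = np.unique(labels, return_counts=True)
        self.majority = vals[np.argmax(counts)]

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.full(len(features), self.majority)

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        return np.zeros(len(features))


def train_svm(features: np.ndarray, labels: np.ndarray, c: float = 1.0):
    """Linear soft-margin SVM with C = 1 (the pipeline's fixed classifier)."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] == 0:
        return _MajorityModel(np.asarray(labels))
    return SVC(kernel="linear", C=c).fit(features, labels)


def decision_scores(model, features: np.ndarray) -> np.ndarray:
    """Signed distances to the separating hyperplane (inputs to the AUC)."""
    return np.asarray(model.decision_function(np.asarray(features, dtype=float)))


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity and specificity (percent, 2 decimals).

    accuracy = (TP+TN)/(TP+FP+TN+FN); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP).  A metric with a zero denominator is
    reported as None (undefined), never as 0.
    """

    def pct(num: int, den: int) -> float | None:
        return None if den == 0 else round(100.0 * num / den, 2)

    return {
        "accuracy": pct(c.tp + c.tn, c.total),
        "sensitivity": pct(c.tp, c.tp + c.fn),
        "specificity": pct(c.tn, c.tn + c.fp),
    }


def compute_auc(scores: np.ndarray, labels: np.ndarray, positive_label=1) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# estimator grid


@dataclass(frozen=True)
class GridPoint:
    """One candidate estimator in the hyperparameter grid.

    ``sparsity_rank`` orders grid points from densest to sparsest and breaks
    inner-CV accuracy ties in favour of the sparsest model.
    """

    name: str
    method: str  # "pc", "pc_thresh", "sr", "gr", "sgr"
    params: tuple = ()
    sparsity_rank: tuple = (0.0,)

    def estimate_features(self, ts: BoldTimeSeries) -> np.ndarray:
        p = dict(self.params)
        if self.method == "pc":
            w = fcn.pearson_fcn(ts)
        elif self.method == "pc_thresh":
            w = fcn.threshold_by_sparsity(fcn.pearson_fcn(ts), p["keep_fraction"])
        elif self.method in ("sr", "gr", "sgr"):
            cfg = SolverConfig(
                lam=p.get("lam", 0.0),
                beta=p.get("beta", 0.0),
                variant=p.get("variant", "regression"),
                max_iter=p.get("max_iter", 1000),
                tol=p.get("tol", 1e-6),
            )
            w = solve(ts, cfg).w
        else:
            raise ValueError(f"unknown estimation method {self.method!r}")
        w = fcn.normalize_weights(fcn.symmetrize(w))
        return vectorize_upper(w).values


def sgr_grid(
    lams: Sequence[float] | None = None,
    betas: Sequence[float] | None = None,
    variant: str = "regression",
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> list[GridPoint]:
    """Full cross of lambda x beta candidates; default 2^-5 ... 2^5 each."""
    if lams is None:
        lams = [2.0**k for k in range(-5, 6)]
    if betas is None:
        betas = [2.0**k for k in range(-5, 6)]
    grid = []
    for lam in lams:
        for beta in betas:
            method = "sgr" if lam > 0 and beta > 0 else ("sr" if lam > 0 else "gr")
            grid.append(
                GridPoint(
                    name=f"{method}(lam={lam:g},beta={beta:g})",
                    method=method,
                    params=(
                        ("lam", lam), ("beta", beta), ("variant", variant),
                        ("max_iter", max_iter), ("tol", tol),
                    ),
                    sparsity_rank=(lam, beta),
                )
            )
    return grid


def pc_threshold_grid(levels: Sequence[float] | None = None) -> list[GridPoint]:
    """PC hard-threshold candidates: 11 sparsity levels 1%, 10%, ..., 100%."""
    if levels is None:
        levels = [0.01] + [k / 10 for k in range(1, 11)]
    return [
        GridPoint(
            name=f"pc_thresh(keep={lv:g})",
            method="pc_thresh",
            params=(("keep_fraction", lv),),
            sparsity_rank=(1.0 - lv,),
        )
        for lv in levels
    ]


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class ClassificationReport:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    auc: float
    confusion: ConfusionCounts
    per_fold_selected: list[np.ndarray] = field(default_factory=list)
    chosen_hyperparams: list[str] = field(default_factory=list)
    scores: np.ndarray | None = None
    predictions: np.ndarray | None = None
    labels: np.ndarray | None = None
    positive_label: object = 1
    fallback_folds: list[int] = field(default_factory=list)
    index_map: list[tuple[int, int]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": round(float(self.auc), 4),
            "confusion": {
                "tp": self.confusion.tp, "fp": self.confusion.fp,
                "tn": self.confusion.tn, "fn": self.confusion.fn,
            },
            "positive_label": str(self.positive_label),
            "chosen_hyperparams": list(self.chosen_hyperparams),
            "fallback_folds": list(self.fallback_folds),
        }


def cohort_features(
    cohort: Sequence[BoldTimeSeries],
    grid: Sequence[GridPoint],
    progress: Callable[[int, int], None] | None = None,
) -> dict[str, np.ndarray]:
    """Estimate edge features for every (grid point, subject) pair, cached."""
    out: dict[str, np.ndarray] = {}
    total = len(grid) * len(cohort)
    done = 0
    for g in grid:
        rows = []
        for ts in cohort:
            rows.append(g.estimate_features(ts))
            done += 1
            if progress is not None:
                progress(done, total)
        out[g.name] = np.vstack(rows)
    return out


def _fit_predict(
    train_f: np.ndarray,
    train_y: np.ndarray,
    test_f: np.ndarray,
    p_threshold: float,
    welch: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Screen on the training set, fit the SVM, predict the test set.

    Selected features are z-scored across the training subjects (the same
    transform is applied to the test subjects): a soft-margin SVM at fixed
    C is scale-sensitive, and raw edge weights vary between subjects on an
    arbitrary scale set by the estimator."""
    mask, _ = ttest_select(train_f, train_y, p_threshold, welch=welch)
    fallback = not mask.any()
    tr, te = train_f[:, mask], test_f[:, mask]
    mu = tr.mean(axis=0) if tr.shape[1] else 0.0
    sd = tr.std(axis=0, ddof=0) if tr.shape[1] else 1.0
    sd = np.where(sd > 0, sd, 1.0) if tr.shape[1] else sd
    tr = (tr - mu) / sd
    te = (te - mu) / sd
    model = train_svm(tr, train_y)
    pred = model.predict(te)
    score = decision_scores(model, te)
    return pred, score, mask, fallback


def _inner_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    p_threshold: float,
    welch: bool,
    inner_cv,
    rng: np.random.Generator,
) -> float:
    """Accuracy of an inner cross-validation run on the training set."""
    n = len(labels)
    if inner_cv == "loo":
        folds = [([j for j in range(n) if j != i], [i]) for i in range(n)]
    else:
        k = int(inner_cv)
        perm = rng.permutation(n)
        chunks = np.array_split(perm, k)
        folds = [
            (np.setdiff1d(perm, c).tolist(), c.tolist()) for c in chunks if len(c)
        ]
    correct = 0
    total = 0
    for tr, te in folds:
        tr_y = labels[tr]
        if len(np.unique(tr_y)) < 2 or min(np.bincount(_codes(tr_y))) < 2:
            continue
        pred, _, _, _ = _fit_predict(
            features[tr], tr_y, features[te], p_threshold, welch
        )
        correct += int(np.sum(pred == labels[te]))
        total += len(te)
    return correct / total if total else 0.0


def _codes(labels: np.ndarray) -> np.ndarray:
    _, inv = np.unique(labels, return_inverse=True)
    return inv


def nested_loocv(
    cohort: Sequence[BoldTimeSeries],
    labels: Sequence,
    estimator_grid: Sequence[GridPoint],
    p_threshold: float = 0.01,
    positive_label=None,
    inner_cv="loo",
    welch: bool = False,
    seed: int = 0,
    features_by_grid: dict[str, np.ndarray] | None = None,
) -> ClassificationReport:
    """Nested leave-one-out cross-validation of the full pipeline.

    Outer LOO over subjects; per outer fold an inner CV on the training set
    picks the estimator grid point with the best inner accuracy (ties go to
    the sparsest model); edge screening and the SVM are then refitted on the
    full training set and the held-out subject is predicted.  The confusion
    matrix, decision scores, per-fold selected-edge masks and per-fold
    chosen hyperparameters are accumulated into the report.

    ``features_by_grid`` may carry precomputed features from
    :func:`cohort_features`; otherwise they are estimated here.
    """
    labels = np.asarray(labels)
    if len(estimator_grid) == 0:
        raise ValueError("estimator grid is empty")
    classes = np.unique(labels)
    if len(classes) != 2 or min(np.bincount(_codes(labels))) < 2:
        raise ValueError("need two classes with at least 2 subjects each")
    if positive_label is None:
        positive_label = "MCI" if "MCI" in classes.astype(str) else classes[1]

    if features_by_grid is None:
        features_by_grid = cohort_features(cohort, estimator_grid)
    n = len(labels)
    rng = np.random.default_rng(seed)

    preds, scores = [], []
    masks, chosen, fallback_folds = [], [], []
    for k in range(n):
        tr = [j for j in range(n) if j != k]
        tr_y = labels[tr]
        best = None
        for g in estimator_grid:
            try:
                acc = _inner_accuracy(
                    features_by_grid[g.name][tr], tr_y, p_threshold, welch,
                    inner_cv, rng,
                )
            except ValueError as exc:
                raise RuntimeError(f"inner CV failed in outer fold {k}") from exc
            key = (acc, g.sparsity_rank)
            if best is None or key > best[0]:
                best = (key, g)
        g = best[1]
        feats = features_by_grid[g.name]
        pred, score, mask, fallback = _fit_predict(
            feats[tr], tr_y, feats[[k]], p_threshold, welch
        )
        preds.append(pred[0])
        scores.append(score[0])
        masks.append(mask)
        chosen.append(g.name)
        if fallback:
            fallback_folds.append(k)

    preds = np.asarray(preds)
    scores = np.asarray(scores)
    # orient decision scores so larger = more positive-class
    svm_classes = np.sort(classes)
    if svm_classes[1] != positive_label:
        scores = -scores
    conf = ConfusionCounts(
        tp=int(np.sum((preds == positive_label) & (labels == positive_label))),
        fp=int(np.sum((preds == positive_label) & (labels != positive_label))),
        tn=int(np.sum((preds != positive_label) & (labels != positive_label))),
        fn=int(np.sum((preds != positive_label) & (labels == positive_label))),
    )
    m = compute_metrics(conf)
    auc = compute_auc(scores, labels == positive_label, positive_label=True)
    n_rois = cohort[0].n_rois if len(cohort) else None
    return ClassificationReport(
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        auc=auc,
        confusion=conf,
        per_fold_selected=masks,
        chosen_hyperparams=chosen,
        scores=scores,
        predictions=preds,
        labels=labels,
        positive_label=positive_label,
        fallback_folds=fallback_folds,
        index_map=upper_index_map(n_rois) if n_rois else [],
    )


def loo_accuracy(
    features: np.ndarray,
    labels: Sequence,
    p_threshold: float = 0.01,
    welch: bool = False,
) -> float:
    """Plain (non-nested) LOO accuracy for one fixed estimator setting.

    Selecting hyperparameters by maximizing this quantity over a grid is
    optimistically biased (the test subjects participate in the choice);
    use :func:`nested_loocv` for honest estimates.
    """
    labels = np.asarray(labels)
    n = len(labels)
    correct = 0
    for k in range(n):
        tr = [j for j in range(n) if j != k]
        pred, _, _, _ = _fit_predict(
            features[tr], labels[tr], features[[k]], p_threshold, welch
        )
        correct += int(pred[0] == labels[k])
    return correct / n


# ---------------------------------------------------------------------------
# consensus connections


def consensus_connections(
    per_fold_masks: Sequence[np.ndarray],
    features: np.ndarray,
    labels: Sequence,
    index_map: Sequence[tuple[int, int]],
    roi_labels: Sequence[str] | None = None,
    group_a=None,
    group_b=None,
):
    """Edges selected in *every* outer fold, with group means and p-values.

    Returns a pandas DataFrame with one row per consensus edge
    (roi_i, roi_j, mean weight per group, full-sample t-test p), sorted by
    ascending p.  An empty table is legitimate (some fold selected nothing).
    """
    import pandas as pd

    if len(per_fold_masks) == 0:
        raise ValueError("need at least one recorded fold")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if group_a is None or group_b is None:
        group_a, group_b = classes[0], classes[1]
    consensus = np.logical_and.reduce(np.vstack(per_fold_masks))
    idx = np.flatnonzero(consensus)
    _, pvals = ttest_select(features, labels, p_threshold=1.1)
    rows = []
    for e in idx:
        i, j = index_map[e]
        li = roi_labels[i] if roi_labels else f"ROI_{i + 1}"
        lj = roi_labels[j] if roi_labels else f"ROI_{j + 1}"
        rows.append(
            {
                "roi_i": li,
                "roi_j": lj,
                f"mean_{group_a}": float(features[labels == group_a, e].mean()),
                f"mean_{group_b}": float(features[labels == group_b, e].mean()),
                "p_value": float(pvals[e]),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["roi_i", "roi_j", f"mean_{group_a}", f"mean_{group_b}", "p_value"],
    )
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
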