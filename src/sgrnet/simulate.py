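"""Seeded synthetic BOLD-like cohorts with known ground-truth connectivity.

The generator realizes the inter-similarity assumption the SGR estimator
exploits: the ground truth is a block-modular sparse Gaussian graphical
model in which nodes of the same module connect to largely the same
partners, so similar nodes have similar rows of the true network.  Each
subject's "BOLD" matrix is drawn i.i.d. row-wise from N(0, precision^-1),
optionally passed through an AR(1) temporal smoother for serial
correlation, plus white observation noise, then column-standardized.

Rows are i.i.d. by default because every estimator in this package
consumes only second-order structure, and i.i.d. sampling admits
closed-form oracles (the partial correlation of the truth is
-P_ij / sqrt(P_ii * P_jj)).  What this emulates — and what it does not
(hemodynamics, scanner noise, spatial structure) — is documented in the
methods note.

The two-group cohort plants a set of within-module edges whose precision
entries differ between groups by a controlled effect size, giving a known
discriminative signal for the classification pipeline to recover.
"""

from __future__ import annotations

import numpy as np

from .fcn import standardize
from .types import BoldTimeSeries, GroundTruthNetwork, SyntheticCohort

__all__ = [
    "make_ground_truth",
    "simulate_bold",
    "make_cohort",
    "partial_correlation_from_precision",
]

_SPD_MIN_EIG = 0.1
_SPD_INCREMENT = 0.05
_SPD_MAX_ATTEMPTS = 100


def _load_diagonal(p: np.ndarray) -> np.ndarray:
    """Add to the diagonal until the smallest eigenvalue reaches 0.1."""
    p = p.copy()
    for _ in range(_SPD_MAX_ATTEMPTS):
        w = np.linalg.eigvalsh(p)
        if w.min() >= _SPD_MIN_EIG:
            return p
        p += (_SPD_INCREMENT + max(0.0, -w.min())) * np.eye(p.shape[0])
    raise RuntimeError("diagonal loading failed to reach positive definiteness")


def partial_correlation_from_precision(p: np.ndarray) -> np.ndarray:
    """Closed-form partial correlations: -P_ij / sqrt(P_ii * P_jj), diag 1."""
    d = np.sqrt(np.diag(p))
    pc = -p / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def make_ground_truth(
    n_rois: int = 20,
    n_modules: int = 4,
    within_density: float = 0.6,
    within_strength: float = 0.3,
    cross_density: float = 0.02,
    cross_strength: float = 0.1,
    seed: int = 0,
) -> GroundTruthNetwork:
    """Block-modular sparse precision matrix with guaranteed SPD.

    Nodes are split into ``n_modules`` contiguous modules.  Within-module
    node pairs receive a precision entry of magnitude ``within_strength``
    with probability ``within_density`` (negative sign, so the implied
    partial correlations are positive and survive the positive-PC
    similarity graph); a few weaker cross-module edges are added at
    ``cross_density``.  The diagonal is loaded until the smallest
    eigenvalue is at least 0.1.
    """
    if n_modules > n_rois:
        raise ValueError("n_modules cannot exceed n_rois")
    if not 0.0 < within_density <= 1.0:
        raise ValueError("within_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    modules = np.repeat(np.arange(n_modules), int(np.ceil(n_rois / n_modules)))[
        :n_rois
    ]
    p = np.eye(n_rois)
    for i in range(n_rois):
        for j in range(i + 1, n_rois):
            same = modules[i] == modules[j]
            dens = within_density if same else cross_density
            if rng.random() < dens:
                strength = within_strength if same else cross_strength
                val = -strength * (0.75 + 0.5 * rng.random())
                p[i, j] = p[j, i] = val
    p = _load_diagonal(p)
    support = np.abs(p - np.diag(np.diag(p))) > 1e-12
    return GroundTruthNetwork(precision=p, support=support, module_assignment=modules)


def simulate_bold(
    truth: GroundTruthNetwork,
    t_volumes: int = 150,
    noise_sd: float = 0.0,
    seed: int = 0,
    ar_coeff: float = 0.0,
    subject_id: str = "subject",
) -> BoldTimeSeries:
    """Draw a T x N signal matrix from the truth's Gaussian model.

    Rows are i.i.d. N(0, precision^-1); ``ar_coeff`` in [0, 1) optionally
    smooths consecutive volumes into an AR(1) process for temporal realism;
    ``noise_sd`` adds white observation noise.  Columns are standardized.
    """
    if t_volumes < 2:
        raise ValueError("need at least 2 volumes")
    rng = np.random.default_rng(seed)
    cov = truth.covariance
    chol = np.linalg.cholesky(cov)
    x = rng.standard_normal((t_volumes, truth.n_rois)) @ chol.T
    if ar_coeff:
        if not 0.0 <= ar_coeff < 1.0:
            raise ValueError("ar_coeff must be in [0, 1)")
        for t in range(1, t_volumes):
            x[t] = ar_coeff * x[t - 1] + np.sqrt(1 - ar_coeff**2) * x[t]
    if noise_sd:
        x = x + noise_sd * rng.standard_normal(x.shape)
    return standardize(BoldTimeSeries(data=x, subject_id=subject_id))


def _perturb_edges(
    p: np.ndarray,
    edges: list[tuple[int, int]],
    effect_size: float,
) -> np.ndarray:
    """Strengthen the planted edges' precision entries by ``effect_size``."""
    out = p.copy()
    for i, j in edges:
        base = out[i, j]
        sign = -1.0 if base >= 0 else np.sign(base)
        out[i, j] = out[j, i] = base + sign * effect_size
    return out


def make_cohort(
    n_per_group: int = 30,
    n_rois: int = 20,
    n_modules: int = 4,
    t_volumes: int = 150,
    n_planted: int = 3,
    effect_size: float = 0.4,
    noise_sd: float = 0.0,
    subject_jitter: float = 0.05,
    seed: int = 0,
    within_density: float = 0.6,
    within_strength: float = 0.3,
    group_names: tuple[str, str] = ("NC", "MCI"),
) -> SyntheticCohort:
    """Two-group cohort differing on ``n_planted`` within-module edges.

    Group A uses the base truth; group B's precision perturbs the planted
    edges by ``effect_size`` (then both diagonals are re-loaded to SPD).
    Per-subject truths are jittered multiplicatively on the off-diagonal
    (relative sd ``subject_jitter``) for inter-subject variability.
    Labels are 0 for group A and 1 for group B; ``group_names`` only
    decorate subject ids.
    """
    rng = np.random.default_rng(seed)
    base = make_ground_truth(
        n_rois=n_rois,
        n_modules=n_modules,
        within_density=within_density,
        within_strength=within_strength,
        seed=int(rng.integers(2**31 - 1)),
    )
    within_edges = [
        (i, j)
        for i in range(n_rois)
        for j in range(i + 1, n_rois)
        if base.support[i, j]
        and base.module_assignment[i] == base.module_assignment[j]
    ]
    if n_planted > len(within_edges):
        raise ValueError(
            f"cannot plant {n_planted} edges; only {len(within_edges)} available"
        )
    chosen = rng.choice(len(within_edges), size=n_planted, replace=False)
    planted = [within_edges[c] for c in sorted(chosen.tolist())]

    p_a = _load_diagonal(base.precision)
    p_b = _load_diagonal(_perturb_edges(base.precision, planted, effect_size))
    truth_a = GroundTruthNetwork(
        precision=p_a,
        support=np.abs(p_a - np.diag(np.diag(p_a))) > 1e-12,
        module_assignment=base.module_assignment,
    )
    truth_b = GroundTruthNetwork(
        precision=p_b,
        support=np.abs(p_b - np.diag(np.diag(p_b))) > 1e-12,
        module_assignment=base.module_assignment,
    )

    subjects: list[BoldTimeSeries] = []
    labels = []
    for label, truth, name in ((0, truth_a, group_names[0]), (1, truth_b, group_names[1])):
        for s in range(n_per_group):
            p_s = truth.precision.copy()
            if subject_jitter:
                off = ~np.eye(n_rois, dtype=bool)
                jit = 1.0 + subject_jitter * rng.standard_normal((n_rois, n_rois))
                jit = (jit + jit.T) / 2.0
                p_s[off] = p_s[off] * jit[off]
                p_s = _load_diagonal(p_s)
            truth_s = GroundTruthNetwork(
                precision=p_s,
                support=np.abs(p_s - np.diag(np.diag(p_s))) > 1e-12,
                module_assignment=truth.module_assignment,
            )
            subjects.append(
                simulate_bold(
                    truth_s,
                    t_volumes=t_volumes,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(2**31 - 1)),
                    subject_id=f"{name}_{s + 1:03d}",
                )
            )
            labels.append(label)
    return SyntheticCohort(
        subjects=subjects,
        labels=np.asarray(labels),
        truth_a=truth_a,
        truth_b=truth_b,
        planted_edges=planted,
        seed=seed,
    )
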