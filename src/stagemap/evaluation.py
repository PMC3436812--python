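"""Quantitative evaluation of embeddings and within-stage subpopulations.

Embeddings are scored by the leave-one-out nearest-neighbour error: the
number of points whose nearest other point (Euclidean distance, ties broken
by smallest index) carries a different class label. Linear baselines (PCA,
ICA) provide reference embeddings. Within one stage, a two-component
Gaussian mixture model splits the cells into candidate subclusters, which
are then characterized by per-gene expression differences and by a Welch
t-test on each cell's minimum data-space distance to a reference population
(e.g. trophectoderm cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA, FastICA
from sklearn.mixture import GaussianMixture

from .exceptions import DegenerateInputError, InvalidInputError


def nearest_neighbour_error(points, labels) -> int:
    """Leave-one-out 1-NN misclassification count.

    For each point the nearest *other* point is found; the return value is
    the number of points whose nearest neighbour has a different label.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.ndim != 2 or points.shape[0] < 2:
        raise InvalidInputError("need at least two points in a 2-D array")
    if labels.shape[0] != points.shape[0]:
        raise InvalidInputError("one label per point required")
    D = cdist(points, points)
    np.fill_diagonal(D, np.inf)
    nn = np.argmin(D, axis=1)  # ties resolved to the smallest index
    return int(np.sum(labels[nn] != labels))


def _canonicalize_ica(S: np.ndarray, mixing: np.ndarray):
    """Fix ICA's sign/order indeterminacy: order components by excess kurtosis
    (descending), then flip each so its first nonzero mixing loading is positive."""
    kurt = stats.kurtosis(S, axis=0, fisher=True, bias=False)
    order = np.argsort(-kurt, kind="stable")
    S = S[:, order]
    mixing = mixing[:, order]
    for k in range(S.shape[1]):
        col = mixing[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            S[:, k] *= -1.0
            mixing[:, k] *= -1.0
    return S


def baseline_embedding(Y, method: str, q: int = 2, seed: int = 0) -> np.ndarray:
    """Linear baseline embedding: ``method`` is ``"pca"`` or ``"ica"``.

    PCA is deterministic; ICA is seeded and canonicalized (component order by
    kurtosis, sign by the first mixing loading) so repeated runs agree.
    Rank-deficient data yield zero-padded trailing components with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    if q >= Y.shape[1]:
        raise InvalidInputError("q must be smaller than the data dimension")
    rank = np.linalg.matrix_rank(Y - Y.mean(axis=0))
    k = min(q, rank)
    if k < q:
        warnings.warn(f"data rank {rank} < q={q}; padding with zero components",
                      stacklevel=2)
    if method == "pca":
        Z = PCA(n_components=k, svd_solver="full").fit_transform(Y)
    elif method == "ica":
        ica = FastICA(n_components=k, whiten="unit-variance", random_state=seed,
                      max_iter=2000, tol=1e-6)
        S = ica.fit_transform(Y)
        Z = _canonicalize_ica(S, ica.mixing_.copy())
    else:
        raise InvalidInputError(f"unknown baseline method {method!r}")
    if k < q:
        Z = np.column_stack([Z, np.zeros((Y.shape[0], q - k))])
    return Z


def gmm_subclusters(points, n_components: int = 2, seed: int = 0,
                    restarts: int = 10) -> np.ndarray:
    """Hard assignment from a full-covariance Gaussian mixture, best of
    ``restarts`` seeded initializations by final log-likelihood."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] <= 2 * n_components:
        raise InvalidInputError("need more than 2 * n_components points")
    if np.allclose(points, points[0]):
        raise DegenerateInputError("all points identical; mixture is undefined")
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=restarts,
        random_state=seed,
        reg_covar=1e-6,
    )
    return gm.fit_predict(points)


def min_distance_to_reference(Y_stage, Y_reference) -> np.ndarray:
    """Per stage cell: minimum Euclidean distance to any reference cell."""
    Y_stage = np.atleast_2d(np.asarray(Y_stage, dtype=float))
    Y_reference = np.atleast_2d(np.asarray(Y_reference, dtype=float))
    if Y_reference.shape[0] == 0:
        raise InvalidInputError("reference set is empty")
    return cdist(Y_stage, Y_reference).min(axis=1)


def subcluster_distance_test(distances_a, distances_b):
    """Welch two-sample t-test; returns (t statistic, two-sided p value).

    Zero variance in both samples with equal means gives (0, 1) by convention.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each sample needs at least two observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class SubclusterResult:
    """Two-way split of one stage's cells with its expression signature."""

    stage_label: object
    assignment: np.ndarray          # binary per cell in the stage
    mean_difference: np.ndarray     # per gene: larger-cluster mean - smaller-cluster mean
    within_sd: np.ndarray           # per gene: SD within the smaller subcluster
    sizes: tuple[int, int]          # (larger, smaller)


def subcluster_expression_profile(Y, assignment, stage_label=None) -> SubclusterResult:
    """Per-gene difference of subcluster means and smaller-subcluster SD.

    Sign convention: mean of the larger subcluster minus mean of the smaller
    one. With equal sizes the cluster whose label sorts first counts as the
    "larger" one. A singleton smaller subcluster reports SD 0 with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    assignment = np.asarray(assignment)
    labs = np.unique(assignment)
    if labs.size != 2:
        raise InvalidInputError("assignment must contain exactly two labels")
    n0 = int(np.sum(assignment == labs[0]))
    n1 = int(np.sum(assignment == labs[1]))
    big, small = (labs[0], labs[1]) if n0 >= n1 else (labs[1], labs[0])
    Yb = Y[assignment == big]
    Ys = Y[assignment == small]
    diff = Yb.mean(axis=0) - Ys.mean(axis=0)
    if Ys.shape[0] < 2:
        warnings.warn("singleton smaller subcluster; within-SD reported as 0",
                      stacklevel=2)
        sd = np.zeros(Y.shape[1])
    else:
        sd = Ys.std(axis=0, ddof=1)
    return SubclusterResult(
        stage_label=stage_label,
        assignment=assignment,
        mean_difference=diff,
        within_sd=sd,
        sizes=(Yb.shape[0], Ys.shape[0]),
    )


def procrustes_align(X, X_ref):
    """Similarity-align X to X_ref (translation + rotation/reflection + scale).

    Returns ``(X_aligned, mean_error)`` where ``mean_error`` is the mean
    per-point Euclidean distance between aligned X and X_ref.
    """
    X = np.asarray(X, dtype=float)
    X_ref = np.asarray(X_ref, dtype=float)
    if X.shape != X_ref.shape:
        raise InvalidInputError("shapes must match for alignment")
    mu_x = X.mean(axis=0)
    mu_r = X_ref.mean(axis=0)
    Xc = X - mu_x
    Rc = X_ref - mu_r
    M = Xc.T @ Rc
    U, s, Vt = np.linalg.svd(M)
    R = U @ Vt
    denom = float(np.sum(Xc**2))
    if denom == 0.0:
        raise DegenerateInputError("X has zero spread; cannot align")
    scale = float(s.sum()) / denom
    aligned = scale * (Xc @ R) + mu_r
    err = float(np.mean(np.linalg.norm(aligned - X_ref, axis=1)))
    return aligned, err


def accuracy_up_to_swap(assignment, truth) -> float:
    """Fraction of points correctly assigned, maximized over a binary label swap."""
    a = np.asarray(assignment)
    t = np.asarray(truth)
    ula, ult = np.unique(a), np.unique(t)
    if ula.size > 2 or ult.size > 2:
        raise InvalidInputError("defined for binary labelings only")
    a01 = (a == ula[-1]).astype(int)
    t01 = (t == ult[-1]).astype(int)
    acc = float(np.mean(a01 == t01))
    return max(acc, 1.0 - acc)
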