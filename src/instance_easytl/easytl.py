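"""EasyTL: intra-domain alignment plus intra-domain programming.

Two phases.  *Intra-domain alignment* recolors source features to the
target's second-order statistics (the CORAL transform), shrinking the
covariance gap between domains.  *Intra-domain programming* then solves a
small linear program for a probability annotation matrix ``W`` (C classes x
n samples, column-stochastic): ``W[c, j]`` is the probability that sample
``j`` belongs to class ``c``, obtained by minimizing the distance-weighted
annotation cost to the (weighted) class centers, subject to every column
summing to one and — optionally — every class receiving at least unit total
mass.  Labels are the per-column argmax.

The weighted variant (class centers computed under per-sample weights) is
what the boosting wrapper calls once per iteration.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from scipy.optimize import linprog
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .domains import LabeledDomain

__all__ = [
    "coral_align",
    "weighted_class_centers",
    "distance_matrix",
    "solve_annotation_matrix",
    "predict_from_annotation",
    "easytl_classify",
    "EasyTLClassifier",
]

#: Column sums of an annotation matrix must match 1 within this tolerance.
COLUMN_SUM_TOL = 1e-8


def _matrix_power_sym(C: np.ndarray, power: float) -> np.ndarray:
    """Fractional power of a symmetric PSD matrix via its eigendecomposition."""
    w, V = eigh(C)
    w = np.clip(w, 1e-12, None)
    return (V * w**power) @ V.T


def coral_align(
    Xs: np.ndarray, Xt: np.ndarray, reg: float = 1.0, align_mean: bool = True
) -> np.ndarray:
    """Align ``Xs`` to the target's first- and second-order statistics.

    The covariance recoloring is
    ``(Xs - mean_s) @ (Cov(Xs)+reg*I)^(-1/2) @ (Cov(Xt)+reg*I)^(1/2) + mean_t``:
    whiten with the source covariance, recolor with the target's, and map
    the source mean onto the target mean.  Mean matching matters for
    log-power features, where per-subject channel gains appear as constant
    per-column offsets; a residual mean gap biases every nearest-center
    decision toward one class by the constant ``2 * offset . (c1 - c0)``.
    Set ``align_mean=False`` for the pure linear recoloring.  The target
    matrix is untouched; ``reg`` ridges both covariances so the whitening
    stays stable when n < D.
    """
    Xs = np.asarray(Xs, dtype=float)
    Xt = np.asarray(Xt, dtype=float)
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError(
            f"feature-count mismatch: source {Xs.shape[1]} vs target {Xt.shape[1]}"
        )
    if not (np.all(np.isfinite(Xs)) and np.all(np.isfinite(Xt))):
        raise ValueError("non-finite values in input")
    if reg < 0:
        raise ValueError("reg must be nonnegative")
    D = Xs.shape[1]
    Cs = np.cov(Xs, rowvar=False).reshape(D, D) + reg * np.eye(D)
    Ct = np.cov(Xt, rowvar=False).reshape(D, D) + reg * np.eye(D)
    A = _matrix_power_sym(Cs, -0.5) @ _matrix_power_sym(Ct, 0.5)
    if not align_mean:
        return Xs @ A
    return (Xs - Xs.mean(axis=0)) @ A + Xt.mean(axis=0)


def weighted_class_centers(
    X: np.ndarray, y: np.ndarray, weights: np.ndarray, classes: np.ndarray | None = None
) -> np.ndarray:
    """Per-class weighted means: row ``c`` is ``sum w_i x_i / sum w_i`` over class c."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    w = np.asarray(weights, dtype=float)
    if not np.all(w > 0):
        raise ValueError("sample weights must be strictly positive")
    if classes is None:
        classes = np.unique(y)
    centers = np.empty((len(classes), X.shape[1]))
    for row, c in enumerate(classes):
        mask = y == c
        total = w[mask].sum()
        if total <= 0:
            raise ValueError(f"class {c} has zero total weight")
        centers[row] = (w[mask, None] * X[mask]).sum(axis=0) / total
    return centers


def distance_matrix(
    centers: np.ndarray, X: np.ndarray, metric: str = "sqeuclidean"
) -> np.ndarray:
    """(C, n) annotation cost: distance from every class center to every sample."""
    if metric not in ("sqeuclidean", "cosine"):
        raise ValueError(f"unknown metric {metric!r}")
    D = cdist(np.asarray(centers, float), np.asarray(X, float), metric=metric)
    # cosine distance can go microscopically negative through rounding
    return np.clip(D, 0.0, None)


def solve_annotation_matrix(
    Dmat: np.ndarray, class_mass_constraint: bool = True
) -> np.ndarray:
    """Solve for the probability annotation matrix ``W``.

    Minimizes ``sum_{c,j} Dmat[c,j] * W[c,j]`` subject to ``W >= 0`` and each
    column summing to one.  With ``class_mass_constraint`` on, each class row
    must additionally keep total mass ``>= 1``, preventing the program from
    annotating a class out of existence; the columns then couple and the
    problem is solved as a sparse LP.  With the flag off the program
    decouples per column and the minimizer is the hard indicator of the
    nearest center (ties to the lowest class index).
    """
    Dmat = np.asarray(Dmat, dtype=float)
    if Dmat.ndim != 2:
        raise ValueError("Dmat must be 2-D (classes x samples)")
    if not np.all(np.isfinite(Dmat)) or np.any(Dmat < 0):
        raise ValueError("Dmat must be finite and nonnegative")
    C, n = Dmat.shape

    if not class_mass_constraint:
        W = _nearest_center_annotation(Dmat)
    else:
        if n < C:
            warnings.warn(
                f"class-mass constraint infeasible with {n} samples < {C} classes; "
                "falling back to nearest-center assignment",
                RuntimeWarning,
            )
            W = _nearest_center_annotation(Dmat)
        else:
            W = _solve_annotation_lp(Dmat)

    _check_annotation_matrix(W)
    return W


def _nearest_center_annotation(Dmat: np.ndarray) -> np.ndarray:
    C, n = Dmat.shape
    W = np.zeros((C, n))
    W[np.argmin(Dmat, axis=0), np.arange(n)] = 1.0
    return W


def _solve_annotation_lp(Dmat: np.ndarray) -> np.ndarray:
    C, n = Dmat.shape
    # variable order: W[c, j] at index c*n + j
    cost = Dmat.ravel()
    A_eq = sparse.kron(np.ones((1, C)), sparse.eye(n), format="csr")  # column sums
    b_eq = np.ones(n)
    A_ub = sparse.kron(sparse.eye(C), -np.ones((1, n)), format="csr")  # -row sums
    b_ub = -np.ones(C)
    res = linprog(
        cost,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        warnings.warn(
            f"annotation LP failed ({res.message}); falling back to nearest-center "
            "assignment",
            RuntimeWarning,
        )
        return _nearest_center_annotation(Dmat)
    W = np.clip(res.x.reshape(C, n), 0.0, None)
    colsums = W.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > COLUMN_SUM_TOL):
        raise RuntimeError("LP solution violates column-stochasticity")
    return W / colsums  # exact renormalization of solver round-off


def _check_annotation_matrix(W: np.ndarray) -> None:
    if np.any(W < 0):
        raise RuntimeError("annotation matrix has negative entries")
    if np.any(np.abs(W.sum(axis=0) - 1.0) > COLUMN_SUM_TOL):
        raise RuntimeError("annotation matrix columns do not sum to one")


def predict_from_annotation(W: np.ndarray) -> np.ndarray:
    """Per-column argmax class index; ties break toward the lowest class index."""
    W = np.asarray(W, dtype=float)
    _check_annotation_matrix(W)
    return np.argmax(W, axis=0)


def _standardize_pool(
    XT: np.ndarray, XS: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-score both matrices with the training pool's per-column statistics."""
    mean = XT.mean(axis=0)
    std = XT.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (XT - mean) / std, (XS - mean) / std, mean, std


def easytl_classify(
    XT: np.ndarray,
    yT: np.ndarray,
    pt: np.ndarray,
    XS: np.ndarray,
    *,
    metric: str = "sqeuclidean",
    class_mass_constraint: bool = True,
    standardize: bool = True,
    classes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One weighted EasyTL pass: label the training pool T and the test pool S.

    Class centers are the ``pt``-weighted means of T.  The annotation LP is
    solved jointly over the concatenation of T's and S's samples, and the
    argmax labels are split back into the T part and the S part.  Log-power
    scales differ per channel, so features are z-scored per column with the
    training pool's statistics first (switchable).
    """
    XT = np.asarray(XT, dtype=float)
    XS = np.asarray(XS, dtype=float)
    pt = np.asarray(pt, dtype=float)
    if pt.shape[0] != XT.shape[0]:
        raise ValueError("pt must align with the rows of XT")
    if XS.shape[1] != XT.shape[1]:
        raise ValueError("feature-count mismatch between T and S")
    if classes is None:
        classes = np.unique(yT)
    if standardize:
        XT, XS, _, _ = _standardize_pool(XT, XS)
    centers = weighted_class_centers(XT, yT, pt, classes=classes)
    Dmat = distance_matrix(centers, np.vstack([XT, XS]), metric=metric)
    W = solve_annotation_matrix(Dmat, class_mass_constraint=class_mass_constraint)
    labels = classes[predict_from_annotation(W)]
    nT = XT.shape[0]
    return labels[:nT], labels[nT:]


class EasyTLClassifier(ClassifierMixin, BaseEstimator):
    """Plain EasyTL as a scikit-learn style transductive classifier.

    ``fit`` stores the labeled source domain; ``predict(X)`` aligns the
    stored source toward the statistics of ``X`` (the target batch), builds
    weighted class centers and solves the annotation LP over ``X``.  Because
    alignment uses the query batch's covariance, prediction is transductive:
    the whole target batch should be passed at once.

    Parameters
    ----------
    align : bool, default=True
        Apply the CORAL recoloring of the source toward the target batch.
    reg : float, default=1.0
        Ridge added to both covariances in the alignment transform.
    metric : {"sqeuclidean", "cosine"}, default="sqeuclidean"
        Annotation cost between class centers and samples.
    class_mass_constraint : bool, default=True
        Keep at least unit probability mass per class row in the LP.
    standardize : bool, default=True
        Z-score features per column (training-pool statistics) before
        centers and distances.
    """

    def __init__(
        self,
        align: bool = True,
        reg: float = 1.0,
        metric: str = "sqeuclidean",
        class_mass_constraint: bool = True,
        standardize: bool = True,
    ):
        self.align = align
        self.reg = reg
        self.metric = metric
        self.class_mass_constraint = class_mass_constraint
        self.standardize = standardize

    def fit(self, X, y, sample_weight=None):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        self.X_ = X
        self.y_ = y
        if sample_weight is None:
            sample_weight = np.ones(X.shape[0])
        self.sample_weight_ = np.asarray(sample_weight, dtype=float)
        if self.sample_weight_.shape != (X.shape[0],):
            raise ValueError("sample_weight must align with the rows of X")
        return self

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = np.asarray(X, dtype=float)
        Xs = self.X_
        if self.align:
            Xs = coral_align(Xs, X, reg=self.reg)
        XT, XS = Xs, X
        if self.standardize:
            XT, XS, _, _ = _standardize_pool(XT, XS)
        centers = weighted_class_centers(
            XT, self.y_, self.sample_weight_, classes=self.classes_
        )
        Dmat = distance_matrix(centers, XS, metric=self.metric)
        W = solve_annotation_matrix(
            Dmat, class_mass_constraint=self.class_mass_constraint
        )
        return self.classes_[predict_from_annotation(W)]

    def fit_predict(self, X, y, X_target, sample_weight=None):
        """Convenience: fit on the source and transductively label the target."""
        return self.fit(X, y, sample_weight=sample_weight).predict(X_target)


def easytl_predict(
    source: LabeledDomain,
    X_target: np.ndarray,
    **params,
) -> np.ndarray:
    """Functional wrapper: plain EasyTL labels for an unlabeled target matrix."""
    clf = EasyTLClassifier(**params)
    return clf.fit_predict(source.X, source.y, X_target)
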