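"""Instance-weighted boosting around EasyTL for cross-subject transfer.

The held-out subject's data (target domain, ``n_t`` samples) is split by a
borrow ratio ``lam``: a stratified fraction ``m = round(lam * n_t)`` of
labeled samples (``Ttd``) joins the pooled source subjects (``Tsd``) to form
the training pool ``T``; the remaining ``l = n_t - m`` samples (``S``) are
the untouched test set.  Each of ``N`` boosting iterations runs one weighted
EasyTL pass with the normalized sample weights ``p_t``, measures the
weighted misclassification rate ``eps_t`` on the borrowed target samples
only, and reweights: misclassified *source* samples shrink by the constant
factor ``beta = 1 / (1 + sqrt(2 ln(n_s) / N))`` while misclassified
*borrowed-target* samples grow by ``1 / beta_t`` with
``beta_t = eps_t / (1 - eps_t)``.  Training thus concentrates on source
samples that resemble the target subject.  The final label of each test
sample is a weighted vote of the last half of the iteration hypotheses,
with weights ``-ln(beta_t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, log, sqrt

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .domains import LabeledDomain
from .easytl import (
    _standardize_pool,
    coral_align,
    distance_matrix,
    easytl_classify,
    predict_from_annotation,
    solve_annotation_matrix,
    weighted_class_centers,
)

__all__ = [
    "DomainSplit",
    "BoostResult",
    "split_domains",
    "init_weights",
    "normalize_weights",
    "weighted_error",
    "beta_factors",
    "update_weights",
    "final_hypothesis",
    "fit_predict",
    "InstanceEasyTL",
]

#: The weighted target-domain error is clipped into this interval: a zero
#: error would zero out beta_t and break the final vote's products, while
#: eps >= 1/2 breaks the boosting assumption.  All N iterations always run.
EPS_CLIP = (1e-10, 0.499)


@dataclass
class DomainSplit:
    """The (Tsd, Ttd, S) partition of a transfer problem.

    ``Tsd`` is the whole source domain; ``idx_borrow``/``idx_test`` index the
    target domain's rows assigned to the borrowed pool Ttd and the test set S.
    """

    source: LabeledDomain
    target: LabeledDomain
    idx_borrow: np.ndarray
    idx_test: np.ndarray
    lam: float
    seed: int | None = None

    @property
    def X_borrow(self) -> np.ndarray:
        return self.target.X[self.idx_borrow]

    @property
    def y_borrow(self) -> np.ndarray:
        return self.target.y[self.idx_borrow]

    @property
    def X_test(self) -> np.ndarray:
        return self.target.X[self.idx_test]

    @property
    def n_source(self) -> int:
        return self.source.n_samples

    @property
    def n_borrow(self) -> int:
        return self.idx_borrow.size


@dataclass
class BoostResult:
    """Final test labels plus the per-iteration boosting history."""

    hf: np.ndarray
    idx_test: np.ndarray
    idx_borrow: np.ndarray
    eps_history: np.ndarray
    beta_t_history: np.ndarray
    beta: float
    h_test_history: np.ndarray  # (N, l) labels on S per iteration
    h_borrow_history: np.ndarray  # (N, m) labels on Ttd per iteration
    # labels on Tsd per iteration: recorded for diagnostics and weight replay,
    # never used by the error or the final vote
    h_source_history: np.ndarray = field(default_factory=lambda: np.empty((0, 0), int))
    config: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return self.eps_history.size


def split_domains(
    source: LabeledDomain,
    target: LabeledDomain,
    lam: float,
    seed: int | None = 0,
) -> DomainSplit:
    """Stratified borrow split of the target domain.

    ``round(lam * n_t)`` target samples, stratified by class, are borrowed
    into the training pool; the rest become the test set.  ``lam = 0``
    borrows nothing and degenerates to plain EasyTL.
    """
    if not 0 <= lam < 1:
        raise ValueError(f"lam must lie in [0, 1), got {lam}")
    if target.y is None:
        raise ValueError("target domain must carry labels to borrow from")
    n_t = target.n_samples
    m = int(round(lam * n_t))
    all_idx = np.arange(n_t)
    if m == 0:
        return DomainSplit(
            source=source,
            target=target,
            idx_borrow=np.empty(0, dtype=int),
            idx_test=all_idx,
            lam=lam,
            seed=seed,
        )
    classes, counts = np.unique(target.y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("target domain must contain both classes when lam > 0")
    idx_borrow, idx_test = train_test_split(
        all_idx,
        train_size=m,
        stratify=target.y,
        random_state=seed,
        shuffle=True,
    )
    borrowed_classes = np.unique(target.y[idx_borrow])
    if len(borrowed_classes) < len(classes):
        raise ValueError(
            f"lam={lam} leaves a class unrepresented in the borrowed pool"
        )
    return DomainSplit(
        source=source,
        target=target,
        idx_borrow=np.sort(idx_borrow),
        idx_test=np.sort(idx_test),
        lam=lam,
        seed=seed,
    )


def init_weights(n_s: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform unit initial weights for the source and borrowed-target pools."""
    if n_s < 1 or m < 0:
        raise ValueError("need n_s >= 1 and m >= 0")
    return np.ones(n_s), np.ones(m)


def normalize_weights(w: np.ndarray) -> np.ndarray:
    """``p_t = w / sum(w)``; rejects non-positive weights."""
    w = np.asarray(w, dtype=float)
    if not np.all(w > 0):
        raise ValueError("weights must be strictly positive")
    return w / w.sum()


def weighted_error(
    h_on_borrow: np.ndarray,
    y_borrow: np.ndarray,
    w_borrow: np.ndarray,
    clip: bool = True,
) -> float:
    """Weighted misclassification rate on the borrowed target pool.

    Normalized by the total borrowed-pool weight (the summation runs over
    Ttd only); clipped into ``EPS_CLIP`` unless ``clip=False``.
    """
    h = np.asarray(h_on_borrow)
    y = np.asarray(y_borrow)
    w = np.asarray(w_borrow, dtype=float)
    if h.shape != y.shape or h.shape != w.shape:
        raise ValueError("h, y, and weights must align")
    if h.size == 0:
        raise ValueError("the borrowed target pool is empty")
    eps = float(np.sum(w * np.abs(h - y)) / np.sum(w))
    if clip:
        eps = float(np.clip(eps, *EPS_CLIP))
    return eps


def beta_factors(eps_t: float, n_s: int, N: int) -> tuple[float, float]:
    """Update factors: ``beta_t = eps/(1-eps)`` and the iteration-independent
    ``beta = 1 / (1 + sqrt(2 ln(n_s) / N))``."""
    if not 0 < eps_t < 0.5:
        raise ValueError(f"eps_t must lie in (0, 0.5), got {eps_t}")
    if n_s < 2:
        raise ValueError("need at least two source samples")
    if N < 1:
        raise ValueError("need N >= 1")
    beta_t = eps_t / (1.0 - eps_t)
    beta = 1.0 / (1.0 + sqrt(2.0 * log(n_s) / N))
    return beta_t, beta


def update_weights(
    w_source: np.ndarray,
    w_borrow: np.ndarray,
    h_source: np.ndarray,
    y_source: np.ndarray,
    h_borrow: np.ndarray,
    y_borrow: np.ndarray,
    beta: float,
    beta_t: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative reweighting step.

    Correctly classified samples keep their weight (exponent zero);
    misclassified source weights shrink by ``beta < 1`` and misclassified
    borrowed-target weights grow by ``1 / beta_t > 1``.
    """
    miss_s = np.abs(np.asarray(h_source) - np.asarray(y_source))
    miss_b = np.abs(np.asarray(h_borrow) - np.asarray(y_borrow))
    new_source = np.asarray(w_source, float) * beta**miss_s
    new_borrow = np.asarray(w_borrow, float) * beta_t ** (-miss_b)
    return new_source, new_borrow


def final_hypothesis(
    h_history: np.ndarray, beta_t_history: np.ndarray, N: int | None = None
) -> np.ndarray:
    """Weighted vote of the last half of the iteration hypotheses.

    A test sample gets label 1 iff the ``-ln(beta_t)``-weighted sum of its
    hypotheses over iterations ``ceil(N/2) .. N`` reaches half the total
    vote weight (evaluated in log space; boundary equality counts as 1).
    """
    h_history = np.asarray(h_history, dtype=float)
    beta_t_history = np.asarray(beta_t_history, dtype=float)
    if N is None:
        N = h_history.shape[0]
    if h_history.shape[0] < N or beta_t_history.shape[0] < N:
        raise ValueError("history shorter than N iterations")
    start = ceil(N / 2) - 1  # iterations are 1-based in the voting rule
    a = -np.log(beta_t_history[start:N])  # positive: beta_t in (0, 1)
    scores = a @ h_history[start:N]
    return (scores >= 0.5 * a.sum()).astype(int)


def fit_predict(
    source: LabeledDomain,
    target: LabeledDomain,
    lam: float = 0.3,
    N: int = 30,
    seed: int | None = 0,
    *,
    align: bool = True,
    reg: float = 1.0,
    metric: str = "sqeuclidean",
    class_mass_constraint: bool = True,
    standardize: bool = True,
) -> BoostResult:
    """Run the full instance-weighted transfer loop and label the test set.

    With ``lam = 0`` there is no borrowed pool to adapt on; a single plain
    (unweighted) EasyTL pass labels the whole target domain.

    Alignment, when enabled, recolors the source once before the loop,
    using the covariance of the entire target domain (the borrowed samples
    plus the unlabeled test set — a legitimate transductive use).
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    if source.y is None:
        raise ValueError("source domain must be labeled")
    if source.n_features != target.n_features:
        raise ValueError("source and target feature counts differ")
    classes = np.unique(source.y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("binary labels {0, 1} required")

    split = split_domains(source, target, lam, seed=seed)
    Xs = source.X
    if align:
        Xs = coral_align(Xs, target.X, reg=reg)

    config = dict(
        lam=lam,
        N=N,
        seed=seed,
        align=align,
        reg=reg,
        metric=metric,
        class_mass_constraint=class_mass_constraint,
        standardize=standardize,
    )

    XS = split.X_test
    if split.n_borrow == 0:
        # plain EasyTL: one unweighted pass over the whole target domain
        pt = normalize_weights(np.ones(split.n_source))
        _, h_S = easytl_classify(
            Xs,
            source.y,
            pt,
            XS,
            metric=metric,
            class_mass_constraint=class_mass_constraint,
            standardize=standardize,
            classes=classes,
        )
        return BoostResult(
            hf=h_S.astype(int),
            idx_test=split.idx_test,
            idx_borrow=split.idx_borrow,
            eps_history=np.empty(0),
            beta_t_history=np.empty(0),
            beta=float("nan"),
            h_test_history=h_S[None, :].astype(int),
            h_borrow_history=np.empty((1, 0), dtype=int),
            h_source_history=np.empty((1, 0), dtype=int),
            config=config,
        )

    XT = np.vstack([Xs, split.X_borrow])
    yT = np.concatenate([source.y, split.y_borrow])
    n_s, m, l = split.n_source, split.n_borrow, split.idx_test.size

    w_sd, w_td = init_weights(n_s, m)
    eps_hist = np.empty(N)
    beta_t_hist = np.empty(N)
    h_test_hist = np.empty((N, l), dtype=int)
    h_borrow_hist = np.empty((N, m), dtype=int)
    h_source_hist = np.empty((N, n_s), dtype=int)
    beta = float("nan")

    for t in range(N):
        p_t = normalize_weights(np.concatenate([w_sd, w_td]))
        h_T, h_S = easytl_classify(
            XT,
            yT,
            p_t,
            XS,
            metric=metric,
            class_mass_constraint=class_mass_constraint,
            standardize=standardize,
            classes=classes,
        )
        h_sd, h_td = h_T[:n_s], h_T[n_s:]
        eps_t = weighted_error(h_td, split.y_borrow, w_td)
        beta_t, beta = beta_factors(eps_t, n_s, N)
        w_sd, w_td = update_weights(
            w_sd, w_td, h_sd, source.y, h_td, split.y_borrow, beta, beta_t
        )
        eps_hist[t] = eps_t
        beta_t_hist[t] = beta_t
        h_test_hist[t] = h_S
        h_borrow_hist[t] = h_td
        h_source_hist[t] = h_sd

    hf = final_hypothesis(h_test_hist, beta_t_hist, N)
    return BoostResult(
        hf=hf,
        idx_test=split.idx_test,
        idx_borrow=split.idx_borrow,
        eps_history=eps_hist,
        beta_t_history=beta_t_hist,
        beta=beta,
        h_test_history=h_test_hist,
        h_borrow_history=h_borrow_hist,
        h_source_history=h_source_hist,
        config=config,
    )


class InstanceEasyTL(ClassifierMixin, BaseEstimator):
    """Instance-weighted EasyTL transfer classifier (scikit-learn style).

    ``fit(X, y, X_target=..., y_target=...)`` runs the boosting loop against
    a labeled target subject; a stratified ``lam`` fraction of the target is
    borrowed into training and the rest is labeled transductively.  After
    fitting, ``labels_`` holds the test-set predictions, ``test_indices_``
    their row indices within the target matrix, and ``result_`` the full
    per-iteration history.  ``predict(X)`` labels fresh target-domain
    samples by re-running the stored voting-half centers on them.

    Parameters
    ----------
    lam : float, default=0.3
        Borrow ratio: fraction of the target subject's samples moved into
        the training pool (``lam = 0`` is plain EasyTL).
    n_iter : int, default=30
        Number of boosting iterations N.
    align, reg, metric, class_mass_constraint, standardize :
        Passed through to the EasyTL pass; see
        :class:`~instance_easytl.easytl.EasyTLClassifier`.
    random_state : int or None, default=0
        Seed for the stratified borrow split (the only randomness).
    """

    def __init__(
        self,
        lam: float = 0.3,
        n_iter: int = 30,
        align: bool = True,
        reg: float = 1.0,
        metric: str = "sqeuclidean",
        class_mass_constraint: bool = True,
        standardize: bool = True,
        random_state: int | None = 0,
    ):
        self.lam = lam
        self.n_iter = n_iter
        self.align = align
        self.reg = reg
        self.metric = metric
        self.class_mass_constraint = class_mass_constraint
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y, X_target=None, y_target=None):
        if X_target is None or y_target is None:
            raise ValueError(
                "InstanceEasyTL.fit requires the target subject: "
                "fit(X, y, X_target=..., y_target=...)"
            )
        source = LabeledDomain(np.asarray(X, float), np.asarray(y, int))
        target = LabeledDomain(np.asarray(X_target, float), np.asarray(y_target, int))
        result = fit_predict(
            source,
            target,
            lam=self.lam,
            N=self.n_iter,
            seed=self.random_state,
            align=self.align,
            reg=self.reg,
            metric=self.metric,
            class_mass_constraint=self.class_mass_constraint,
            standardize=self.standardize,
        )
        self.classes_ = np.unique(source.y)
        self.result_ = result
        self.labels_ = result.hf
        self.test_indices_ = result.idx_test
        self.borrow_indices_ = result.idx_borrow
        self._store_vote_state(source, target, result)
        return self

    def _store_vote_state(self, source, target, result):
        """Cache per-voting-iteration class centers so predict(X) can re-vote."""
        Xs = source.X
        if self.align:
            Xs = coral_align(Xs, target.X, reg=self.reg)
        if result.n_iterations == 0:  # lam = 0: single unweighted pass
            XT, yT = Xs, source.y
            XT_use, _, mean, std = _standardize_pool(XT, target.X)
            if not self.standardize:
                XT_use = XT
            centers = weighted_class_centers(
                XT_use, yT, np.ones(XT.shape[0]), classes=self.classes_
            )
            self._vote_centers_ = centers[None, :, :]
            self._vote_weights_ = np.ones(1)
        else:
            XT = np.vstack([Xs, target.X[result.idx_borrow]])
            yT = np.concatenate([source.y, target.y[result.idx_borrow]])
            y_b = target.y[result.idx_borrow]
            XT_use, _, mean, std = _standardize_pool(XT, target.X[result.idx_test])
            if not self.standardize:
                XT_use = XT
            N = result.n_iterations
            start = ceil(N / 2) - 1
            # replay the multiplicative weight trajectory from the recorded
            # hypotheses to recover each voting iteration's p_t
            w_sd, w_td = init_weights(source.n_samples, result.idx_borrow.size)
            centers_list, vote_w = [], []
            for t in range(N):
                p_t = normalize_weights(np.concatenate([w_sd, w_td]))
                if t >= start:
                    centers_list.append(
                        weighted_class_centers(XT_use, yT, p_t, classes=self.classes_)
                    )
                    vote_w.append(-log(result.beta_t_history[t]))
                w_sd, w_td = update_weights(
                    w_sd,
                    w_td,
                    result.h_source_history[t],
                    source.y,
                    result.h_borrow_history[t],
                    y_b,
                    result.beta,
                    result.beta_t_history[t],
                )
            self._vote_centers_ = np.stack(centers_list)
            self._vote_weights_ = np.asarray(vote_w)
        self._scale_mean_ = mean if self.standardize else None
        self._scale_std_ = std if self.standardize else None

    def predict(self, X=None):
        """Vote the stored iteration centers over fresh target-domain samples.

        With ``X=None``, return the transductive test-set labels from ``fit``.
        """
        check_is_fitted(self, "labels_")
        if X is None:
            return self.labels_
        X = np.asarray(X, dtype=float)
        if self._scale_mean_ is not None:
            X = (X - self._scale_mean_) / self._scale_std_
        votes = np.empty((self._vote_centers_.shape[0], X.shape[0]), dtype=int)
        for k, centers in enumerate(self._vote_centers_):
            Dmat = distance_matrix(centers, X, metric=self.metric)
            W = solve_annotation_matrix(
                Dmat, class_mass_constraint=self.class_mass_constraint
            )
            votes[k] = predict_from_annotation(W)
        a = self._vote_weights_
        scores = a @ votes
        return self.classes_[(scores >= 0.5 * a.sum()).astype(int)]

    def score_test(self, y_target) -> float:
        """Accuracy of the transductive labels against the target's true labels."""
        check_is_fitted(self, "labels_")
        y_target = np.asarray(y_target, dtype=int)
        return float(np.mean(self.labels_ == y_target[self.test_indices_]))
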