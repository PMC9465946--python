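"""Supervised transfer-learning procedures: CORAL, Per-Class CORAL,
Subspace Alignment, and head re-training.

CORAL seeks a linear map ``A`` minimizing ``||A^T C_s A - C_t||_F^2`` between
source and target feature covariances; the closed-form optimum is the
whiten-then-recolor map

    A* = (U_s Sigma_s^{+1/2} U_s^T) (U_t[1:r] Sigma_t[1:r]^{1/2} U_t[1:r]^T)

with ``r = min(rank C_s, rank C_t)``.  Per-Class CORAL fits one such map per
sleep stage.  Subspace Alignment projects both domains onto their top-k PCA
bases and aligns them with ``M = V_s^T V_t``.  Head re-training stands in
for re-training the dense layer nearest the output of a frozen network: a
multinomial logistic head on fixed features.

The DDC reference trainer lives in :mod:`sleeptransfer.ddc`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ShapeMismatchError,
    UsageError,
)
from .features import (
    FeatureTable,
    SubspaceBasis,
    default_shrinkage,
    empirical_covariance,
    matrix_rank_sym,
    pca_basis,
    symmetric_power,
)


@dataclass
class LinearAdaptation:
    """A fitted linear domain transform.

    ``kind`` is one of ``coral`` (single matrix ``A``), ``per_class_coral``
    (class -> matrix map plus a global fallback), or ``subspace_align``
    (bases ``V_s``, ``V_t`` and aligner ``M = V_s^T V_t``).
    """

    kind: str
    A: np.ndarray | None = None
    class_transforms: dict | None = None
    class_means_source: dict | None = None
    class_means_target: dict | None = None
    fallback_classes: list = field(default_factory=list)
    V_s: SubspaceBasis | None = None
    V_t: SubspaceBasis | None = None
    M: np.ndarray | None = None
    rank_used: int = 0
    shrinkage: float = 0.0
    recenter: str = "none"
    mean_source: np.ndarray | None = None
    mean_target: np.ndarray | None = None

    def to_json(self) -> str:
        def enc(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        payload = {
            "kind": self.kind,
            "A": enc(self.A),
            "class_transforms": (
                {str(k): enc(v) for k, v in self.class_transforms.items()}
                if self.class_transforms
                else None
            ),
            "class_means_source": (
                {str(k): enc(v) for k, v in self.class_means_source.items()}
                if self.class_means_source
                else None
            ),
            "class_means_target": (
                {str(k): enc(v) for k, v in self.class_means_target.items()}
                if self.class_means_target
                else None
            ),
            "fallback_classes": [str(c) for c in self.fallback_classes],
            "V_s": enc(self.V_s.basis) if self.V_s is not None else None,
            "V_t": enc(self.V_t.basis) if self.V_t is not None else None,
            "M": enc(self.M),
            "rank_used": self.rank_used,
            "shrinkage": self.shrinkage,
            "recenter": self.recenter,
            "mean_source": enc(self.mean_source),
            "mean_target": enc(self.mean_target),
        }
        return json.dumps(payload)


def _coral_matrix(Cs: np.ndarray, Ct: np.ndarray) -> tuple[np.ndarray, int]:
    """Closed-form CORAL optimum for given covariances."""
    r = min(matrix_rank_sym(Cs), matrix_rank_sym(Ct))
    whiten = symmetric_power(Cs, -0.5, pseudo=True)
    # recolor with the top-r spectral part of C_t
    Ct = 0.5 * (Ct + Ct.T)
    w, V = np.linalg.eigh(Ct)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    wr = np.where(np.arange(len(w)) < r, np.clip(w, 0.0, None), 0.0)
    recolor = (V * np.sqrt(wr)) @ V.T
    return whiten @ recolor, r


def fit_coral(
    Xs: FeatureTable,
    Xt: FeatureTable,
    shrinkage: float | None = None,
    recenter: str = "none",
) -> LinearAdaptation:
    """Fit the CORAL transform aligning source covariance to target.

    ``shrinkage=None`` applies the default ridge ``1e-6 * trace(C)/d`` to
    each covariance before the closed form (guards downstream inverses);
    pass ``0.0`` to disable.  ``recenter`` controls what happens to the mean
    after the covariance-aligning map: ``"none"`` leaves the transformed
    source zero-meaned, ``"source"`` restores the source mean (the canonical
    CORAL behavior — the transform recolors covariance and does not touch
    means), and ``"target"`` moves it onto the target mean.
    """
    if Xs.d != Xt.d:
        raise ShapeMismatchError(f"dimension mismatch: {Xs.d} vs {Xt.d}")
    if recenter not in ("none", "source", "target"):
        raise ValueError("recenter must be 'none', 'source' or 'target'")
    cs = empirical_covariance(Xs.features)
    ct = empirical_covariance(Xt.features)
    if shrinkage is None:
        lam = max(default_shrinkage(cs.cov), default_shrinkage(ct.cov))
    else:
        lam = float(shrinkage)
    Cs = cs.cov + lam * np.eye(Xs.d)
    Ct = ct.cov + lam * np.eye(Xt.d)
    A, r = _coral_matrix(Cs, Ct)
    return LinearAdaptation(
        kind="coral",
        A=A,
        rank_used=r,
        shrinkage=lam,
        recenter=recenter,
        mean_source=cs.mean,
        mean_target=ct.mean,
    )


def apply_coral(adapt: LinearAdaptation, Xs: FeatureTable) -> FeatureTable:
    """Transform source rows as ``(x - mean_s) @ A`` (+ target mean if set)."""
    if adapt.kind != "coral":
        raise UsageError(f"apply_coral got a '{adapt.kind}' transform")
    if Xs.d != adapt.A.shape[0]:
        raise ShapeMismatchError("feature dimension does not match transform")
    Z = (Xs.features - adapt.mean_source) @ adapt.A
    if adapt.recenter == "target":
        Z = Z + adapt.mean_target
    elif adapt.recenter == "source":
        Z = Z + adapt.mean_source
    return Xs.with_features(Z)


def fit_per_class_coral(
    Xs: FeatureTable,
    Xt: FeatureTable,
    shrinkage: float | None = None,
    recenter: str = "none",
    min_class_n: int | None = None,
    allow_global_fallback: bool = True,
) -> LinearAdaptation:
    """One CORAL transform per sleep stage.

    A class gets its own transform only if it appears in both domains with at
    least ``min_class_n`` samples on each side (default ``d + 2``, below
    which the class covariance is necessarily singular); other classes fall
    back to the global CORAL transform and are recorded in
    ``fallback_classes``.
    """
    if Xs.d != Xt.d:
        raise ShapeMismatchError(f"dimension mismatch: {Xs.d} vs {Xt.d}")
    if min_class_n is None:
        min_class_n = Xs.d + 2
    global_fit = fit_coral(Xs, Xt, shrinkage=shrinkage, recenter=recenter)
    transforms: dict = {}
    means_s: dict = {}
    means_t: dict = {}
    fallback = []
    rank_used = global_fit.rank_used
    for c in np.unique(np.concatenate([Xs.labels, Xt.labels])):
        ms = Xs.labels == c
        mt = Xt.labels == c
        if ms.sum() >= min_class_n and mt.sum() >= min_class_n:
            sub_fit = fit_coral(
                Xs.subset(ms), Xt.subset(mt), shrinkage=shrinkage, recenter=recenter
            )
            transforms[c] = sub_fit.A
            means_s[c] = sub_fit.mean_source
            means_t[c] = sub_fit.mean_target
            rank_used = min(rank_used, sub_fit.rank_used)
        else:
            fallback.append(c)
            if not allow_global_fallback:
                continue
            transforms[c] = global_fit.A
            means_s[c] = (
                Xs.features[ms].mean(axis=0) if ms.any() else global_fit.mean_source
            )
            means_t[c] = (
                Xt.features[mt].mean(axis=0) if mt.any() else global_fit.mean_target
            )
    if not allow_global_fallback and len(fallback) == len(transforms) + len(fallback):
        if not transforms:
            raise DegenerateDataError(
                "no class satisfies the per-class sample threshold and the "
                "global fallback is disabled"
            )
    return LinearAdaptation(
        kind="per_class_coral",
        class_transforms=transforms,
        class_means_source=means_s,
        class_means_target=means_t,
        fallback_classes=fallback,
        rank_used=rank_used,
        shrinkage=global_fit.shrinkage,
        recenter=recenter,
        mean_source=global_fit.mean_source,
        mean_target=global_fit.mean_target,
        A=global_fit.A,
    )


def apply_per_class_coral(adapt: LinearAdaptation, Xs: FeatureTable) -> FeatureTable:
    """Transform each source class with its own matrix.

    With ``recenter='target'`` each class lands on its target class mean.
    With ``recenter='source'`` or ``'none'`` the class keeps its *source*
    mean (the transform is covariance-only): collapsing every class onto the
    origin, as the global zero-mean convention would, would discard all
    label geometry.
    """
    if adapt.kind != "per_class_coral":
        raise UsageError(f"apply_per_class_coral got a '{adapt.kind}' transform")
    Z = np.empty_like(Xs.features)
    for c in np.unique(Xs.labels):
        m = Xs.labels == c
        A = adapt.class_transforms.get(c, adapt.A)
        mu_s = adapt.class_means_source.get(c, adapt.mean_source)
        centered = (Xs.features[m] - mu_s) @ A
        if adapt.recenter == "target":
            mu_t = adapt.class_means_target.get(c, adapt.mean_target)
            Z[m] = centered + mu_t
        else:
            Z[m] = centered + mu_s
    return Xs.with_features(Z)


def fit_subspace_alignment(
    Xs: FeatureTable, Xt: FeatureTable, k: int = 100
) -> LinearAdaptation:
    """Subspace Alignment: PCA bases for each domain and ``M = V_s^T V_t``.

    ``k`` defaults to 100 and is truncated to ``min(rank_s, rank_t)`` with a
    warning when the data cannot support it.  Source rows map to
    ``(x V_s) M``; target rows map to ``x V_t``; both outputs have width k.
    """
    if Xs.d != Xt.d:
        raise ShapeMismatchError(f"dimension mismatch: {Xs.d} vs {Xt.d}")
    if Xs.n < 2 or Xt.n < 2:
        raise InsufficientDataError("subspace alignment needs >= 2 samples per side")
    Vs = pca_basis(Xs.features, k)
    Vt = pca_basis(Xt.features, k)
    k_eff = min(Vs.k, Vt.k)
    if k_eff < k:
        warnings.warn(
            f"subspace dimension truncated from {k} to data rank {k_eff}",
            stacklevel=2,
        )
    Vs = SubspaceBasis(Vs.basis[:, :k_eff], Vs.explained_variance[:k_eff], True)
    Vt = SubspaceBasis(Vt.basis[:, :k_eff], Vt.explained_variance[:k_eff], True)
    M = Vs.basis.T @ Vt.basis
    return LinearAdaptation(kind="subspace_align", V_s=Vs, V_t=Vt, M=M, rank_used=k_eff)


def project_source(adapt: LinearAdaptation, Xs: FeatureTable) -> FeatureTable:
    """Aligned source coordinates ``(x V_s) M``."""
    if adapt.kind != "subspace_align":
        raise UsageError(f"project_source got a '{adapt.kind}' transform")
    return Xs.with_features(Xs.features @ adapt.V_s.basis @ adapt.M)


def project_target(adapt: LinearAdaptation, Xt: FeatureTable) -> FeatureTable:
    """Target coordinates ``x V_t``."""
    if adapt.kind != "subspace_align":
        raise UsageError(f"project_target got a '{adapt.kind}' transform")
    return Xt.with_features(Xt.features @ adapt.V_t.basis)


@dataclass
class HeadClassifier:
    """Multinomial logistic head over fixed features.

    Stands in for the single dense layer adjacent to the output that remains
    trainable when the rest of a pre-trained network is frozen.  Training
    minimizes mean cross-entropy plus ``l2 * ||W||^2`` with L-BFGS.
    """

    weights: np.ndarray
    bias: np.ndarray
    classes: np.ndarray
    n_iter: int
    final_loss: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.decision_function(X)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.decision_function(X), axis=1)]

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


# L2 weight of the reference training recipe (pre-training hyperparameter
# search value carried over to transfer-learning heads): 10 ** -6.9.
DEFAULT_HEAD_L2 = 10 ** -6.9


def train_head(
    X: np.ndarray,
    y: np.ndarray,
    l2: float = DEFAULT_HEAD_L2,
    max_iter: int = 1000,
    seed: int = 0,
) -> HeadClassifier:
    """Train the multinomial logistic head to convergence.

    Deterministic given ``seed`` (L-BFGS itself is deterministic; the seed
    covers any stochastic solver fallback).  ``l2`` is the weight of the
    squared-norm penalty added to the *mean* cross-entropy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateDataError("head training needs >= 2 classes")
    n = X.shape[0]
    # sklearn minimizes  0.5 w'w + C * sum_i loss_i ; our objective is
    # mean loss + l2 ||w||^2  ==  (1/(2 l2 n)) scaling of C.
    C = 1.0 / (2.0 * l2 * n)
    clf = LogisticRegression(
        penalty="l2",
        C=C,
        solver="lbfgs",
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    W = clf.coef_.T
    b = clf.intercept_
    if classes.size == 2 and W.shape[1] == 1:
        # expand sklearn's binary parameterization to one column per class
        W = np.hstack([-0.5 * W, 0.5 * W])
        b = np.array([-0.5 * b[0], 0.5 * b[0]])
    P = np.clip(
        clf.predict_proba(X)[np.arange(n), np.searchsorted(classes, y)], 1e-300, None
    )
    loss = float(-np.mean(np.log(P)) + l2 * np.sum(clf.coef_ ** 2))
    return HeadClassifier(
        weights=W,
        bias=b,
        classes=clf.classes_,
        n_iter=int(np.max(clf.n_iter_)),
        final_loss=loss,
    )
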