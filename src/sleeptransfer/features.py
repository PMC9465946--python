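"""Feature-table data model, file I/O and shared linear-algebra utilities.

A :class:`FeatureTable` holds one 30-s-epoch-by-feature matrix together with
per-sample sleep-stage labels, a source/target domain tag, and subject and
recording identifiers.  All adaptation algorithms and transferability
measures in this package consume these tables.

Conventions used throughout the package:

* samples are rows; linear transforms act on the right (``x_hat = x @ A``);
* rank decisions use a single global threshold of ``1e-10 * sigma_max`` on
  singular values;
* PCA basis columns are sign-fixed so the largest-magnitude entry of each
  column is positive, making decompositions deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDataError,
    FeatureParseError,
    InsufficientDataError,
    SchemaError,
)

RANK_RTOL = 1e-10
"""Relative singular-value threshold used for every rank decision."""

META_COLUMNS = ("label", "domain", "subject", "recording")

DEFAULT_DIALECT = {c: c for c in META_COLUMNS}


@dataclass
class FeatureTable:
    """n x d feature matrix with per-sample metadata.

    Parameters
    ----------
    features
        Real matrix of shape ``(n, d)``; unitless learned-feature activations.
    labels
        Length-n class codes (e.g. the 5 sleep stages W/N1/N2/N3/REM).
    domain
        Length-n tags, each ``"source"`` or ``"target"``.
    subject
        Length-n subject/group identifiers.
    recording
        Length-n within-subject recording identifiers.
    """

    features: np.ndarray
    labels: np.ndarray
    domain: np.ndarray
    subject: np.ndarray
    recording: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise SchemaError("features must be a 2-D array")
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise SchemaError("feature matrix must have n >= 1 and d >= 1")
        if not np.all(np.isfinite(self.features)):
            bad = int(np.argwhere(~np.isfinite(self.features))[0, 0])
            raise FeatureParseError(
                f"non-finite feature value at row {bad}", row=bad
            )
        for name in ("labels", "domain", "subject", "recording"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise SchemaError(
                    f"{name} has length {arr.shape}, expected ({n},)"
                )
            setattr(self, name, arr)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        """Row-subset by boolean mask or index array."""
        return FeatureTable(
            self.features[mask],
            self.labels[mask],
            self.domain[mask],
            self.subject[mask],
            self.recording[mask],
        )

    def with_features(self, features: np.ndarray) -> "FeatureTable":
        """Same metadata, new feature matrix (row count must match)."""
        return FeatureTable(
            np.asarray(features, dtype=float),
            self.labels,
            self.domain,
            self.subject,
            self.recording,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"feature_{j}": self.features[:, j] for j in range(self.d)}
        cols["label"] = self.labels
        cols["domain"] = self.domain
        cols["subject"] = self.subject
        cols["recording"] = self.recording
        return pd.DataFrame(cols)


@dataclass
class CovarianceModel:
    """Sample mean/covariance with rank and shrinkage metadata."""

    mean: np.ndarray
    cov: np.ndarray
    rank: int
    shrinkage: float


@dataclass
class SubspaceBasis:
    """Orthonormal PCA basis (columns) with explained variances."""

    basis: np.ndarray
    explained_variance: np.ndarray
    truncated: bool = field(default=False)

    @property
    def k(self) -> int:
        return self.basis.shape[1]


def load_feature_table(path, dialect: dict | None = None) -> FeatureTable:
    """Read a feature-table CSV.

    The expected header is ``feature_0..feature_{d-1}`` plus the metadata
    columns ``label, domain, subject, recording`` (names remappable through
    ``dialect``).  Non-numeric or non-finite feature cells are rejected with
    the offending row index.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    for key in META_COLUMNS:
        col = dialect[key]
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}'")
    meta_cols = [dialect[k] for k in META_COLUMNS]
    feat_cols = [c for c in df.columns if c not in meta_cols]
    if not feat_cols:
        raise SchemaError("no feature columns found")
    feats = df[feat_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad = ~np.isfinite(feats)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise FeatureParseError(
            f"non-numeric or non-finite feature value at row {row}", row=row
        )
    return FeatureTable(
        feats,
        df[dialect["label"]].to_numpy(),
        df[dialect["domain"]].to_numpy(),
        df[dialect["subject"]].to_numpy(),
        df[dialect["recording"]].to_numpy(),
    )


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a table as CSV with 17 significant digits (lossless round trip)."""
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_matrix(M: np.ndarray, path) -> None:
    """Write any matrix as whitespace-delimited text (debugging aid)."""
    np.savetxt(path, np.atleast_2d(np.asarray(M, dtype=float)), fmt="%.17g")


def empirical_covariance(X: np.ndarray, shrinkage: float = 0.0) -> CovarianceModel:
    """Unbiased sample covariance ``(1/(n-1)) * scatter + shrinkage * I``.

    For ``n == 1`` the covariance is ``shrinkage * I``.  The reported rank is
    that of the centered data matrix (singular values above
    ``RANK_RTOL * sigma_max``), i.e. of the *unshrunk* covariance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if d == 0:
        raise DegenerateDataError("empty input: d = 0")
    if shrinkage < 0:
        raise ValueError("shrinkage must be >= 0")
    mean = X.mean(axis=0)
    Xc = X - mean
    if n >= 2:
        cov = (Xc.T @ Xc) / (n - 1)
    else:
        cov = np.zeros((d, d))
    sv = np.linalg.svd(Xc, compute_uv=False) if n >= 1 else np.array([])
    if sv.size and sv[0] > 0:
        rank = int(np.sum(sv > RANK_RTOL * sv[0]))
    else:
        rank = 0
    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry
    if shrinkage > 0:
        cov = cov + shrinkage * np.eye(d)
    return CovarianceModel(mean=mean, cov=cov, rank=rank, shrinkage=float(shrinkage))


def default_shrinkage(cov: np.ndarray) -> float:
    """Default ridge used inside adaptation fits: ``1e-6 * trace(cov)/d``."""
    d = cov.shape[0]
    return 1e-6 * float(np.trace(cov)) / d


def pca_basis(X: np.ndarray, k: int) -> SubspaceBasis:
    """Top-``k`` principal directions of ``X`` (rows are samples).

    ``X`` is centered internally.  If ``k`` exceeds the data rank it is
    truncated to the rank and the truncation flagged on the result.  Each
    basis column is sign-fixed so its largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        raise InsufficientDataError("PCA needs at least 2 samples")
    if k < 1:
        raise ValueError("k must be >= 1")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > RANK_RTOL * s[0])) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise DegenerateDataError("all samples identical: no principal directions")
    truncated = k > rank
    k_eff = min(k, rank)
    V = Vt[:k_eff].T
    # deterministic sign: largest-|entry| of each column made positive
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(k_eff)])
    signs[signs == 0] = 1.0
    V = V * signs
    var = (s[:k_eff] ** 2) / (n - 1)
    return SubspaceBasis(basis=V, explained_variance=var, truncated=truncated)


def symmetric_power(C: np.ndarray, power: float, pseudo: bool = True) -> np.ndarray:
    """Matrix power of a symmetric PSD matrix via eigendecomposition.

    Eigenvalues below ``RANK_RTOL * max_eig`` are treated as zero; with
    ``pseudo`` they are dropped (Moore-Penrose convention for negative
    powers), otherwise a zero eigenvalue with a negative power raises.
    """
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    wmax = max(w.max(), 0.0) if w.size else 0.0
    tol = RANK_RTOL * wmax
    keep = w > tol
    if power < 0 and not pseudo and not keep.all():
        raise DegenerateDataError("singular matrix with negative power")
    wp = np.zeros_like(w)
    wp[keep] = w[keep] ** power
    return (V * wp) @ V.T


def matrix_rank_sym(C: np.ndarray) -> int:
    """Rank of a symmetric matrix under the global threshold."""
    w = np.abs(np.linalg.eigvalsh(0.5 * (C + C.T)))
    if w.size == 0 or w.max() == 0:
        return 0
    return int(np.sum(w > RANK_RTOL * w.max()))
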