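"""Transferability measures: LEEP, H-score, hypothesis margin,
cross-dataset silhouette, TDAS, and MMD-as-a-measure.

All six estimate, before any re-training is done, how well a model carried
over from a source domain should perform on a target domain.  LEEP and
H-score look at the target data through the pre-trained model (posteriors or
extracted features); the remaining four compare the geometry of source and
target feature clouds directly, treating *dataset membership* — not the
sleep stage — as the class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .adaptation import fit_subspace_alignment, project_source, project_target
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
)
from .features import FeatureTable
from .mmd import median_heuristic, mmd2_quadratic

_LOG_FLOOR = 1e-300


@dataclass
class PosteriorMatrix:
    """Row-stochastic source-label posteriors with paired target labels.

    ``theta[i, z]`` is the pre-trained model's probability that target
    sample ``i`` carries source label ``z``; ``target_labels[i]`` is the true
    target label.
    """

    theta: np.ndarray
    target_labels: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.target_labels = np.asarray(self.target_labels)
        if self.theta.ndim != 2 or self.theta.shape[1] < 2:
            raise ParameterError("theta must be n x Z with Z >= 2")
        n = self.theta.shape[0]
        if n < 1 or self.target_labels.shape != (n,):
            raise ParameterError("target_labels must have length n >= 1")
        if np.any(self.theta < -1e-12) or np.any(self.theta > 1 + 1e-12):
            raise ParameterError("posterior entries must lie in [0, 1]")
        if np.max(np.abs(self.theta.sum(axis=1) - 1.0)) > 1e-8:
            raise ParameterError("posterior rows must sum to 1 within 1e-8")


@dataclass
class TransferabilityReport:
    """One measure evaluation: name, parameters, value, sample sizes."""

    measure: str
    value: float
    params: dict = field(default_factory=dict)
    n_source: int = 0
    n_target: int = 0

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "value": self.value,
            "params": self.params,
            "n_source": self.n_source,
            "n_target": self.n_target,
        }


def load_posterior_matrix(path) -> PosteriorMatrix:
    """Read a posterior CSV with header ``p_0..p_{Z-1},label``."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    if "label" not in df.columns:
        raise ParameterError("posterior CSV must have a 'label' column")
    p_cols = [c for c in df.columns if c != "label"]
    return PosteriorMatrix(
        theta=df[p_cols].to_numpy(float),
        target_labels=df["label"].to_numpy(),
    )


def write_posterior_matrix(post: PosteriorMatrix, path) -> None:
    """Write a posterior matrix as CSV (header ``p_0..p_{Z-1},label``)."""
    import pandas as pd

    cols = {f"p_{z}": post.theta[:, z] for z in range(post.theta.shape[1])}
    cols["label"] = post.target_labels
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def leep(post: PosteriorMatrix) -> float:
    """Log Expected Empirical Prediction.

    Builds the empirical joint ``P(y, z) = mean over samples with true label
    y of theta_z`` and the marginal ``P(z)``, forms the conditional
    ``P(y | z)``, and returns the mean log-likelihood of the resulting
    empirical Bayes classifier on the target samples.  Always <= 0; equals 0
    only for a perfect one-hot predictor.
    """
    theta, y = post.theta, post.target_labels
    n, Z = theta.shape
    classes = np.unique(y)
    P_z = theta.mean(axis=0)
    P_yz = np.vstack([theta[y == c].sum(axis=0) / n for c in classes])
    with np.errstate(divide="ignore", invalid="ignore"):
        P_y_given_z = np.where(P_z > 0, P_yz / P_z, 0.0)
    y_idx = np.searchsorted(classes, y)
    lik = np.einsum("nz,nz->n", theta, P_y_given_z[y_idx])
    return float(np.mean(np.log(np.maximum(lik, _LOG_FLOOR))))


def h_score(phi: np.ndarray, y: np.ndarray, pseudoinverse: bool = True) -> float:
    """H-score: ``tr(cov(phi)^{-1} cov(E[phi | Y]))``.

    The between-class covariance uses class-frequency weights around the
    global mean, matching the law-of-total-covariance decomposition (both
    covariances use the population 1/n convention; the trace ratio is
    insensitive to a common normalization).  With ``pseudoinverse`` (default)
    or whenever the total covariance is singular, the inverse is replaced by
    the Moore-Penrose pseudoinverse.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    y = np.asarray(y)
    n = phi.shape[0]
    if n < 2:
        raise InsufficientDataError("H-score needs n >= 2")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateDataError("H-score needs >= 2 classes")
    mu = phi.mean(axis=0)
    Xc = phi - mu
    cov_total = (Xc.T @ Xc) / n
    cov_between = np.zeros_like(cov_total)
    for c in classes:
        m = y == c
        diff = phi[m].mean(axis=0) - mu
        cov_between += (m.sum() / n) * np.outer(diff, diff)
    if pseudoinverse:
        inv = np.linalg.pinv(cov_total, rcond=1e-10, hermitian=True)
    else:
        inv = np.linalg.inv(cov_total)
    return float(np.trace(inv @ cov_between))


def _stride_downsample(n: int, factor: int, rng: np.random.Generator) -> np.ndarray:
    """Every ``factor``-th index starting from a seeded circular offset."""
    if factor <= 1:
        return np.arange(n)
    offset = int(rng.integers(factor))
    return np.arange(offset % n, n, factor)


def hypothesis_margin(
    Xs_feats: np.ndarray,
    Xt_feats: np.ndarray,
    downsample: int = 10,
    seed: int = 0,
) -> float:
    """Mean hypothesis margin between source and target feature clouds.

    Dataset membership plays the role of the class: for each point in the
    union, ``nearhit`` is its nearest neighbor in the same dataset (the
    point itself excluded) and ``nearmiss`` its nearest neighbor in the
    other dataset.  The returned value is the mean over the union of
    ``(||x - nearmiss|| - ||x - nearhit||) / 2``: positive when the two
    clouds are separated, negative when each point's closest neighbor tends
    to sit in the other dataset.

    Both datasets are independently downsampled with a deterministic stride
    from a seeded circular offset (default factor 10).
    """
    Xs = np.atleast_2d(np.asarray(Xs_feats, dtype=float))
    Xt = np.atleast_2d(np.asarray(Xt_feats, dtype=float))
    rng = np.random.default_rng(seed)
    Xs = Xs[_stride_downsample(Xs.shape[0], downsample, rng)]
    Xt = Xt[_stride_downsample(Xt.shape[0], downsample, rng)]
    if Xs.shape[0] < 2 or Xt.shape[0] < 2:
        raise InsufficientDataError(
            "each dataset must retain >= 2 points after downsampling"
        )
    D_ss = cdist(Xs, Xs)
    D_tt = cdist(Xt, Xt)
    D_st = cdist(Xs, Xt)
    np.fill_diagonal(D_ss, np.inf)
    np.fill_diagonal(D_tt, np.inf)
    margins_s = 0.5 * (D_st.min(axis=1) - D_ss.min(axis=1))
    margins_t = 0.5 * (D_st.min(axis=0) - D_tt.min(axis=1))
    return float(np.concatenate([margins_s, margins_t]).mean())


def silhouette_cross(Xs_feats: np.ndarray, Xt_feats: np.ndarray) -> float:
    """Cross-dataset silhouette: separation of source vs target clouds.

    For each point, ``A`` is its mean L2 distance to the rest of its own
    dataset and ``B`` its mean distance to the other dataset; the silhouette
    of the point is ``(B - A) / max(A, B)`` (0 when ``A = B = 0``), and the
    score is the mean over the union.  Lies in [-1, 1]; approaches 1 for
    well-separated clouds and 0 for fully overlapping ones.
    """
    Xs = np.atleast_2d(np.asarray(Xs_feats, dtype=float))
    Xt = np.atleast_2d(np.asarray(Xt_feats, dtype=float))
    ns, nt = Xs.shape[0], Xt.shape[0]
    if ns < 2 or nt < 2:
        raise InsufficientDataError("both sets need >= 2 points")
    D_ss = cdist(Xs, Xs)
    D_tt = cdist(Xt, Xt)
    D_st = cdist(Xs, Xt)
    A = np.concatenate(
        [D_ss.sum(axis=1) / (ns - 1), D_tt.sum(axis=1) / (nt - 1)]
    )
    B = np.concatenate([D_st.mean(axis=1), D_st.mean(axis=0)])
    denom = np.maximum(A, B)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0, (B - A) / denom, 0.0)
    return float(s.mean())


def tdas(
    Xs: FeatureTable,
    Xt: FeatureTable,
    k: int = 100,
    eps_scale: float = 1.0,
    adapt=None,
) -> float:
    """Target Density Around Source in the aligned PCA subspace.

    Fits Subspace Alignment (or reuses a supplied fit), computes the
    similarity ``sim(x_s, x_t) = (x_s V_s M) . (x_t V_t)`` for every
    source/target pair, and returns the average over source samples of the
    number of target samples with similarity at least ``eps_scale * m``,
    where ``m`` is the median pairwise Euclidean distance within the target.
    The dot-product similarity is compared against the distance-derived
    threshold exactly as defined; no normalization is applied.
    """
    if eps_scale <= 0:
        raise ParameterError("eps_scale must be > 0")
    m = float(np.median(pdist(Xt.features)))
    if m <= 0:
        raise DegenerateDataError("degenerate target: zero median distance")
    if adapt is None:
        adapt = fit_subspace_alignment(Xs, Xt, k=k)
    S = project_source(adapt, Xs).features
    T = project_target(adapt, Xt).features
    sims = S @ T.T
    counts = (sims >= eps_scale * m).sum(axis=1)
    return float(counts.mean())


def mmd_measure(
    Xs: FeatureTable | np.ndarray,
    Xt: FeatureTable | np.ndarray,
    gamma_scale: float = 1.0,
) -> float:
    """Squared MMD (quadratic estimator) as a transferability measure.

    The RBF bandwidth comes from the median heuristic on the pooled
    source+target features, scaled by ``gamma_scale`` in {0.1, 1, 10}.
    """
    Fs = Xs.features if isinstance(Xs, FeatureTable) else np.asarray(Xs, float)
    Ft = Xt.features if isinstance(Xt, FeatureTable) else np.asarray(Xt, float)
    spec = median_heuristic(np.vstack([Fs, Ft]), scale=gamma_scale)
    return mmd2_quadratic(Fs, Ft, spec).mmd2


def evaluate_measures(
    Xs: FeatureTable,
    Xt: FeatureTable,
    posteriors: PosteriorMatrix | None = None,
    subspace_k: int = 100,
    downsample: int = 10,
    seed: int = 0,
) -> list[TransferabilityReport]:
    """Evaluate the full measure battery on a source/target pair.

    Returns MMD at gamma scales {0.1, 1, 10}, TDAS at epsilon scales
    {0.1, 1, 10}, cross-dataset silhouette, hypothesis margin, the H-score
    of the target features/labels, and (when posteriors from a
    source-trained model are supplied) LEEP.
    """
    ns, nt = Xs.n, Xt.n
    reports: list[TransferabilityReport] = []
    for s in (0.1, 1.0, 10.0):
        reports.append(
            TransferabilityReport(
                "mmd", mmd_measure(Xs, Xt, gamma_scale=s),
                {"gamma_scale": s}, ns, nt,
            )
        )
    import warnings

    with warnings.catch_warnings():
        # k defaulting above the data rank is routine here; the truncated
        # width is reported in the params of each TDAS record
        warnings.simplefilter("ignore", UserWarning)
        sa = fit_subspace_alignment(Xs, Xt, k=subspace_k)
    for s in (0.1, 1.0, 10.0):
        reports.append(
            TransferabilityReport(
                "tdas", tdas(Xs, Xt, k=subspace_k, eps_scale=s, adapt=sa),
                {"eps_scale": s, "k": sa.rank_used}, ns, nt,
            )
        )
    reports.append(
        TransferabilityReport(
            "silhouette", silhouette_cross(Xs.features, Xt.features), {}, ns, nt
        )
    )
    reports.append(
        TransferabilityReport(
            "hypothesis_margin",
            hypothesis_margin(Xs.features, Xt.features, downsample, seed),
            {"downsample": downsample}, ns, nt,
        )
    )
    reports.append(
        TransferabilityReport(
            "h_score", h_score(Xt.features, Xt.labels), {}, ns, nt
        )
    )
    if posteriors is not None:
        reports.append(
            TransferabilityReport("leep", leep(posteriors), {}, ns, nt)
        )
    return reports
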