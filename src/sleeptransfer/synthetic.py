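"""Synthetic domain-shifted, multi-subject, class-imbalanced feature data.

The generator emulates the learned-feature tables this package's algorithms
consume in practice: activations extracted from 30-s EEG epochs of a
multi-subject sleep study, with five imbalanced stages, a handful of
recordings per subject, and a parametric source-to-target shift standing in
for the change from clinical to wearable acquisition.

Generative model (all draws deterministic from ``seed``):

* class means are ordered along a shared "sleep depth / amplitude" axis
  (the direction of the baseline activation level): Wake sits at the
  high-amplitude end, N3 at the low end, with N1 and REM close together in
  between — the arrangement that makes adjacent-stage confusions (and the
  notorious N1/REM confusion) the dominant error mode, as in real staging;
  a random per-class offset orthogonal-ish to the axis gives each stage an
  identity beyond depth;
* per-subject random mean offsets (inter-subject variability);
* isotropic within-class Gaussian noise;
* the target domain displaces every class mean by ``shift`` within-class
  standard deviations along the attenuation direction — from the global
  feature mean toward the origin, i.e. essentially *down the depth axis*.
  This emulates the amplitude attenuation of a lower-SNR wearable forehead
  channel relative to a clinical montage, whose well-known consequence is
  that attenuated wake resembles light sleep: the shift produces real
  stage-label conflicts between domains rather than moving the target into
  empty feature space.  The target class-mean configuration can additionally
  be rotated in a seeded random 2-plane (``rotation_angle``) and its noise
  covariance scaled by ``cov_scale``.

Because ``shift`` enters only as a deterministic additive term, configs
differing only in ``shift`` share every random draw: the shift family is
coupled, which the monotonicity tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError, ParameterError
from .features import FeatureTable


def default_sleep_priors() -> np.ndarray:
    """Imbalanced 5-stage prior [W, N1, N2, N3, REM], N2-dominant.

    The values are a documented convention of this generator (roughly the
    stage proportions of a healthy adult night, N2 near half), not estimates
    from any particular study.
    """
    return np.array([0.15, 0.08, 0.45, 0.17, 0.15])


@dataclass
class ShiftConfig:
    """Parameters of the source/target generative model.

    ``shift`` is the target class-mean displacement in units of
    ``within_class_sd``; ``rotation_angle`` (radians) rotates the target
    class-mean configuration in a random 2-plane; ``cov_scale`` multiplies
    the target noise covariance.  ``feature_mean`` is the baseline positive
    activation level added to every dimension (see module docstring).
    """

    n_classes: int = 5
    dim: int = 10
    class_priors: np.ndarray | None = None
    class_mean_spread: float = 1.5
    within_class_sd: float = 1.0
    shift: float = 0.0
    rotation_angle: float = 0.0
    cov_scale: float = 1.0
    subject_sd: float = 0.3
    n_subjects: int = 24
    recordings_per_subject: tuple[int, int] = (1, 6)
    epochs_per_recording: int = 120
    feature_mean: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_priors is None:
            if self.n_classes == 5:
                self.class_priors = default_sleep_priors()
            else:
                self.class_priors = np.full(self.n_classes, 1.0 / self.n_classes)
        self.class_priors = np.asarray(self.class_priors, dtype=float)
        if self.n_classes < 2:
            raise ConfigError("need at least 2 classes")
        if self.class_priors.shape != (self.n_classes,):
            raise ConfigError("class_priors length must equal n_classes")
        if np.any(self.class_priors < 0) or abs(self.class_priors.sum() - 1) > 1e-12:
            raise ConfigError("class_priors must be a simplex (sum to 1)")
        for name in ("within_class_sd", "cov_scale", "class_mean_spread"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.subject_sd < 0:
            raise ConfigError("subject_sd must be >= 0")
        lo, hi = self.recordings_per_subject
        if not (1 <= lo <= hi):
            raise ConfigError("recordings_per_subject must satisfy 1 <= lo <= hi")
        min_epochs = self.n_subjects * lo * self.epochs_per_recording
        if min_epochs < self.n_classes:
            raise ConfigError(
                f"infeasible config: at most {min_epochs} samples per domain "
                f"for {self.n_classes} classes"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_priors"] = self.class_priors.tolist()
        d["recordings_per_subject"] = list(self.recordings_per_subject)
        return d


# Stage positions on the depth/amplitude axis for the 5 AASM stages
# [W, N1, N2, N3, REM]: Wake highest, N3 lowest, REM near N1 (their EEG
# features are famously similar).  Other class counts use an even spacing.
_STAGE_DEPTHS = np.array([1.0, 0.35, -0.25, -1.0, 0.2])


def _class_means(cfg: ShiftConfig, rng: np.random.Generator) -> np.ndarray:
    """Class means: depth ordering along the amplitude axis + random offsets.

    Per dimension, class ``c`` sits at ``spread * depth_c`` along the
    all-ones (baseline/amplitude) direction plus an isotropic random offset
    of half that scale.
    """
    if cfg.n_classes == 5:
        depth = _STAGE_DEPTHS
    else:
        depth = np.linspace(1.0, -1.0, cfg.n_classes)
    offsets = 0.5 * rng.standard_normal((cfg.n_classes, cfg.dim))
    return cfg.class_mean_spread * (depth[:, None] * np.ones(cfg.dim) + offsets)


def _rotation_matrix(d: int, angle: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation by ``angle`` in a random 2-plane (identity off-plane)."""
    a = rng.standard_normal(d)
    b = rng.standard_normal(d)
    e1 = a / np.linalg.norm(a)
    b = b - (b @ e1) * e1
    e2 = b / np.linalg.norm(b)
    c, s = np.cos(angle), np.sin(angle)
    P1 = np.outer(e1, e1)
    P2 = np.outer(e2, e2)
    return (
        np.eye(d)
        + (c - 1.0) * (P1 + P2)
        + s * (np.outer(e2, e1) - np.outer(e1, e2))
    )


def _sample_domain(
    prefix: str,
    domain: str,
    class_means: np.ndarray,
    baseline: np.ndarray,
    cfg: ShiftConfig,
    noise_sd: float,
    rng: np.random.Generator,
) -> FeatureTable:
    feats, labels, subjects, recordings = [], [], [], []
    lo, hi = cfg.recordings_per_subject
    stage_names = np.array(["W", "N1", "N2", "N3", "REM"]) if cfg.n_classes == 5 \
        else np.array([f"C{i}" for i in range(cfg.n_classes)])
    for s in range(cfg.n_subjects):
        offset = cfg.subject_sd * rng.standard_normal(cfg.dim)
        n_rec = int(rng.integers(lo, hi + 1))
        for r in range(n_rec):
            y = rng.choice(cfg.n_classes, size=cfg.epochs_per_recording,
                           p=cfg.class_priors)
            noise = noise_sd * rng.standard_normal(
                (cfg.epochs_per_recording, cfg.dim)
            )
            feats.append(baseline + class_means[y] + offset + noise)
            labels.append(stage_names[y])
            subjects.append(np.full(cfg.epochs_per_recording, f"{prefix}{s:02d}"))
            recordings.append(
                np.full(cfg.epochs_per_recording, f"r{r + 1}")
            )
    n_total = sum(len(x) for x in labels)
    return FeatureTable(
        np.vstack(feats),
        np.concatenate(labels),
        np.full(n_total, domain),
        np.concatenate(subjects),
        np.concatenate(recordings),
    )


def make_domain_pair(cfg: ShiftConfig) -> tuple[FeatureTable, FeatureTable]:
    """Generate a (source, target) pair of feature tables.

    Fully reproducible from ``cfg.seed``; see the module docstring for the
    generative model and how the target differs from the source.
    """
    rng = np.random.default_rng(cfg.seed)
    mu = _class_means(cfg, rng)
    baseline = cfg.feature_mean * np.ones(cfg.dim)
    # all directions below are drawn unconditionally so the random stream is
    # identical across configs that differ only in shift/rotation/cov_scale
    fallback = rng.standard_normal(cfg.dim)
    R = _rotation_matrix(cfg.dim, cfg.rotation_angle, rng)
    g0 = baseline + cfg.class_priors @ mu
    norm = np.linalg.norm(g0)
    if norm > 1e-8:
        u = -g0 / norm
    else:
        u = fallback / np.linalg.norm(fallback)
    mu_target = (mu @ R.T) + cfg.shift * cfg.within_class_sd * u
    source = _sample_domain(
        "src", "source", mu, baseline, cfg, cfg.within_class_sd, rng
    )
    target = _sample_domain(
        "tgt", "target", mu_target, baseline, cfg,
        cfg.within_class_sd * np.sqrt(cfg.cov_scale), rng,
    )
    return source, target


def make_posteriors(
    y: np.ndarray,
    accuracy: float,
    Z: int = 5,
    concentration: float = 20.0,
    seed: int = 0,
) -> "PosteriorMatrix":
    """Synthetic softmax posteriors of a source-trained model.

    For each sample a predicted source label is drawn: the label aligned
    with the true class with probability ``accuracy``, otherwise uniform
    over the remaining labels.  The posterior row is then a Dirichlet draw
    with parameter ``1 + concentration * onehot(predicted)``, so larger
    ``concentration`` peaks the row on the prediction;
    ``concentration = numpy.inf`` gives exact one-hot rows.
    """
    from .transferability import PosteriorMatrix

    y = np.asarray(y)
    n = y.shape[0]
    classes = np.unique(y)
    K = classes.size
    if Z < 2:
        raise ParameterError("Z must be >= 2")
    if not (1.0 / K - 1e-12 <= accuracy <= 1.0 + 1e-12):
        raise ParameterError(f"accuracy must lie in [1/K, 1] = [{1 / K:.3f}, 1]")
    rng = np.random.default_rng(seed)
    aligned = np.searchsorted(classes, y) % Z
    correct = rng.random(n) < accuracy
    offs = rng.integers(1, Z, size=n)  # uniform over the Z-1 other labels
    pred = np.where(correct, aligned, (aligned + offs) % Z)
    if np.isinf(concentration):
        theta = np.zeros((n, Z))
        theta[np.arange(n), pred] = 1.0
    else:
        alpha = np.ones((n, Z))
        alpha[np.arange(n), pred] += concentration
        g = rng.standard_gamma(alpha)
        theta = g / g.sum(axis=1, keepdims=True)
    return PosteriorMatrix(theta=theta, target_labels=y)
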