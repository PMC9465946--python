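"""Leave-one-subject-out benchmark of the adaptation algorithms, with
accuracy/kappa aggregation, best-algorithm tallies, paired t-tests against
the head-retraining baseline, and Spearman correlation of every
transferability measure with per-fold accuracy.

Protocol, per held-out target subject:

1. the remaining target subjects form the target training portion;
2. when an algorithm trains on source and target simultaneously, a balanced
   source subset is drawn (first recording per subject, then every n-th
   recording so the subset size matches the number of target training
   recordings);
3. each algorithm is fitted on source + target-train and its head evaluated
   on the held-out subject (accuracy and Cohen's kappa);
4. every transferability measure is computed on the balanced source against
   the target *training* portion only — never on the held-out subject.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger("sleeptransfer.benchmark")

from .adaptation import (
    apply_coral,
    apply_per_class_coral,
    fit_coral,
    fit_per_class_coral,
    fit_subspace_alignment,
    project_source,
    project_target,
    train_head,
)
from .ddc import ddc_reference_train
from .errors import (
    ConfigError,
    DegenerateDataError,
    InsufficientDataError,
    ShapeMismatchError,
)
from .features import FeatureTable
from .transferability import PosteriorMatrix, evaluate_measures, leep

ALGORITHMS = ("head_retrain", "coral", "per_class_coral", "subspace_align", "ddc")


def cohens_kappa(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``.

    ``p_e`` is the chance agreement from the product of the two marginal
    label distributions.  A degenerate ``p_e = 1`` returns 1 when the
    observed agreement is also perfect and raises otherwise.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 1:
        raise ShapeMismatchError("y_true and y_pred must be equal-length 1-D")
    n = y_true.size
    p_o = float(np.mean(y_true == y_pred))
    classes = np.unique(np.concatenate([y_true, y_pred]))
    p_t = np.array([np.mean(y_true == c) for c in classes])
    p_p = np.array([np.mean(y_pred == c) for c in classes])
    p_e = float(p_t @ p_p)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise DegenerateDataError("kappa undefined: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value uses the t approximation.  Zero rank variance on
    either side makes the correlation undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InsufficientDataError("spearman needs equal-length vectors, n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateDataError("zero variance in ranks: correlation undefined")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on the differences ``a - b``.

    Zero-variance differences (including the constant-shift case) leave the
    statistic undefined and raise rather than silently returning 0 or inf.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InsufficientDataError("paired t-test needs equal-length vectors, n >= 2")
    diff = a - b
    if np.all(diff == diff[0]):
        raise DegenerateDataError("zero-variance differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def tally_best(folds: list[dict]) -> dict[str, float]:
    """Fraction of folds each algorithm wins on accuracy; ties split equally.

    ``folds`` is a list of ``{algorithm: accuracy}`` maps, one per fold;
    every fold must score the same full set of algorithms.
    """
    if not folds:
        raise InsufficientDataError("no folds to tally")
    algos = sorted(folds[0])
    wins = {a: 0.0 for a in algos}
    for fold in folds:
        if sorted(fold) != algos:
            raise ConfigError("every fold must score the same algorithms")
        best = max(fold.values())
        tied = [a for a in algos if fold[a] == best]
        for a in tied:
            wins[a] += 1.0 / len(tied)
    return {a: wins[a] / len(folds) for a in algos}


@dataclass
class BenchmarkResult:
    """Per-fold scores, per-fold measures, and aggregate statistics."""

    folds: list = field(default_factory=list)       # (subject, algorithm, acc, kappa)
    measures: list = field(default_factory=list)    # (subject, measure-dict)
    summary: dict = field(default_factory=dict)     # algo -> {acc_mean, ...}
    tallies: dict = field(default_factory=dict)
    ttests: dict = field(default_factory=dict)      # algo -> {t, p} vs baseline
    correlations: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def accuracies(self, algorithm: str) -> np.ndarray:
        return np.array(
            [acc for _, a, acc, _ in self.folds if a == algorithm]
        )

    def measure_values(self, key: str) -> np.ndarray:
        return np.array([m[key] for _, m in self.measures])

    def measure_keys(self) -> list[str]:
        return sorted(self.measures[0][1]) if self.measures else []

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(
            {
                "folds": self.folds,
                "measures": self.measures,
                "summary": self.summary,
                "tallies": self.tallies,
                "ttests": self.ttests,
                "correlations": self.correlations,
                "config": self.config,
            },
            indent=indent,
        )

    @classmethod
    def from_json(cls, text: str) -> "BenchmarkResult":
        d = json.loads(text)
        return cls(
            folds=[tuple(f) for f in d["folds"]],
            measures=[(s, m) for s, m in d["measures"]],
            summary=d["summary"],
            tallies=d["tallies"],
            ttests=d["ttests"],
            correlations=d["correlations"],
            config=d.get("config", {}),
        )


def balanced_source_subset(source: FeatureTable, n_target_recordings: int) -> FeatureTable:
    """Representative source subset matched to the target recording count.

    Keeps only the first recording of every source subject (avoids biasing
    toward subjects with many recordings), then takes every n-th of those
    recordings with ``n = floor(#source recordings / #target recordings)``,
    truncated to the target count.
    """
    if n_target_recordings < 1:
        raise ConfigError("need at least one target recording")
    pairs = sorted(set(zip(source.subject, source.recording)))
    first_rec: dict = {}
    for subj, rec in pairs:
        first_rec.setdefault(subj, rec)
    recordings = sorted(first_rec.items())  # (subject, first recording)
    step = max(1, len(recordings) // n_target_recordings)
    chosen = recordings[::step][:n_target_recordings]
    mask = np.zeros(source.n, dtype=bool)
    for subj, rec in chosen:
        mask |= (source.subject == subj) & (source.recording == rec)
    return source.subset(mask)


def _fit_and_score(
    algorithm: str,
    src: FeatureTable,
    tgt_train: FeatureTable,
    tgt_test: FeatureTable,
    head_cfg: dict,
    seed: int,
):
    """Train one algorithm and return (accuracy, kappa) on the held-out set."""
    l2 = head_cfg.get("l2", 10**-6.9)
    max_iter = head_cfg.get("max_iter", 500)
    recenter = head_cfg.get("recenter", "source")
    sa_k = head_cfg.get("subspace_k", 100)

    if algorithm == "head_retrain":
        head = train_head(tgt_train.features, tgt_train.labels, l2, max_iter, seed)
        pred = head.predict(tgt_test.features)
    elif algorithm == "coral":
        fit = fit_coral(src, tgt_train, recenter=recenter)
        src_t = apply_coral(fit, src)
        X = np.vstack([src_t.features, tgt_train.features])
        y = np.concatenate([src_t.labels, tgt_train.labels])
        head = train_head(X, y, l2, max_iter, seed)
        pred = head.predict(tgt_test.features)
    elif algorithm == "per_class_coral":
        fit = fit_per_class_coral(src, tgt_train, recenter=recenter)
        src_t = apply_per_class_coral(fit, src)
        X = np.vstack([src_t.features, tgt_train.features])
        y = np.concatenate([src_t.labels, tgt_train.labels])
        head = train_head(X, y, l2, max_iter, seed)
        pred = head.predict(tgt_test.features)
    elif algorithm == "subspace_align":
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_subspace_alignment(src, tgt_train, k=sa_k)
        src_p = project_source(fit, src)
        tgt_p = project_target(fit, tgt_train)
        X = np.vstack([src_p.features, tgt_p.features])
        y = np.concatenate([src_p.labels, tgt_p.labels])
        head = train_head(X, y, l2, max_iter, seed)
        pred = head.predict(project_target(fit, tgt_test).features)
    elif algorithm == "ddc":
        model = ddc_reference_train(
            src, None, tgt_train, None,
            hidden_width=head_cfg.get("ddc_hidden", 16),
            mmd_weight=head_cfg.get("ddc_weight", 1.0),
            epochs=head_cfg.get("ddc_epochs", 20),
            seed=seed,
        )
        pred = model.predict(tgt_test.features)
    else:
        raise ConfigError(f"unknown algorithm '{algorithm}'")
    acc = float(np.mean(pred == tgt_test.labels))
    kap = cohens_kappa(tgt_test.labels, pred)
    return acc, kap


def loso_benchmark(
    source: FeatureTable,
    target: FeatureTable,
    algorithms: list[str] = ("head_retrain", "coral", "per_class_coral", "subspace_align"),
    measure_cfg: dict | None = None,
    head_cfg: dict | None = None,
    seed: int = 0,
) -> BenchmarkResult:
    """Run the leave-one-subject-out protocol on a source/target pair.

    Returns the filled :class:`BenchmarkResult` with per-fold scores,
    per-fold transferability measures (training portion only), summary
    statistics, best-algorithm tallies, paired t-tests of each algorithm
    against ``head_retrain`` (when it was run), and measure/accuracy
    Spearman correlations.  Deterministic given ``seed``.
    """
    head_cfg = dict(head_cfg or {})
    measure_cfg = dict(measure_cfg or {})
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ConfigError(f"unknown algorithms: {sorted(unknown)}")
    subjects = np.unique(target.subject)
    if subjects.size < 2:
        raise ConfigError("target must contain at least 2 subjects")
    rng = np.random.default_rng(seed)
    result = BenchmarkResult(
        config={
            "algorithms": list(algorithms),
            "head": head_cfg,
            "measures": measure_cfg,
            "seed": seed,
        }
    )
    cfg_hash = hashlib.sha256(
        json.dumps(result.config, sort_keys=True).encode()
    ).hexdigest()[:12]
    logger.info(
        "LOSO benchmark start: %d target subjects, seed=%d, config=%s",
        subjects.size, seed, cfg_hash,
    )
    sa_k = measure_cfg.get("subspace_k", head_cfg.get("subspace_k", 100))
    downsample = measure_cfg.get("downsample", 10)
    for held in subjects:
        fold_seed = int(rng.integers(2**31))
        test_mask = target.subject == held
        tgt_test = target.subset(test_mask)
        tgt_train = target.subset(~test_mask)
        n_train_rec = len(set(zip(tgt_train.subject, tgt_train.recording)))
        src_bal = balanced_source_subset(source, n_train_rec)

        mdict: dict[str, float] = {}
        reports = evaluate_measures(
            src_bal, tgt_train, posteriors=None,
            subspace_k=sa_k, downsample=downsample, seed=fold_seed,
        )
        for rep in reports:
            key = rep.measure
            if rep.measure == "mmd":
                key = f"mmd_gamma_{rep.params['gamma_scale']:g}"
            elif rep.measure == "tdas":
                key = f"tdas_eps_{rep.params['eps_scale']:g}"
            mdict[key] = rep.value
        src_head = train_head(
            src_bal.features, src_bal.labels,
            head_cfg.get("l2", 10**-6.9), head_cfg.get("max_iter", 500), fold_seed,
        )
        post = PosteriorMatrix(
            theta=src_head.predict_proba(tgt_train.features),
            target_labels=tgt_train.labels,
        )
        mdict["leep"] = leep(post)
        result.measures.append((str(held), mdict))

        for algo in algorithms:
            acc, kap = _fit_and_score(
                algo, src_bal, tgt_train, tgt_test, head_cfg, fold_seed
            )
            result.folds.append((str(held), algo, acc, kap))
        logger.info(
            "fold %s done: %s", held,
            {a: round(acc, 3) for s, a, acc, _ in result.folds
             if s == str(held)},
        )

    # aggregates
    per_fold = []
    for held in subjects:
        per_fold.append(
            {a: acc for s, a, acc, _ in result.folds if s == str(held)}
        )
    result.tallies = tally_best(per_fold)
    for algo in algorithms:
        accs = result.accuracies(algo)
        kaps = np.array([k for _, a, _, k in result.folds if a == algo])
        result.summary[algo] = {
            "accuracy_mean": float(accs.mean()),
            "accuracy_sd": float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
            "kappa_mean": float(kaps.mean()),
            "kappa_sd": float(kaps.std(ddof=1)) if kaps.size > 1 else 0.0,
        }
    if "head_retrain" in algorithms:
        base = result.accuracies("head_retrain")
        for algo in algorithms:
            if algo == "head_retrain":
                continue
            try:
                t, p = paired_ttest(result.accuracies(algo), base)
                result.ttests[algo] = {"t": t, "p": p}
            except DegenerateDataError:
                result.ttests[algo] = {"t": None, "p": None}
    result.correlations = correlate_measures(result)
    return result


def correlate_measures(
    result: BenchmarkResult, bonferroni_family: int | None = None
) -> dict:
    """Spearman r/p of each measure with accuracy, per algorithm and pooled.

    The ``overall`` entry pools (measure value, accuracy) pairs across
    algorithms.  When at least 3 folds are available and ranks are
    non-degenerate; undefined cells are reported as ``None``.  Significance
    flags use a Bonferroni family of ``#measures x (#algorithms + 1)`` by
    default.
    """
    if not result.measures:
        return {}
    keys = result.measure_keys()
    algos = sorted({a for _, a, _, _ in result.folds})
    fold_order = [s for s, _ in result.measures]
    out: dict = {}
    if bonferroni_family is None:
        bonferroni_family = len(keys) * (len(algos) + 1)
    alpha_adj = 0.05 / max(bonferroni_family, 1)
    for key in keys:
        vals = result.measure_values(key)
        out[key] = {}
        pooled_x, pooled_y = [], []
        for algo in algos:
            accs = {s: acc for s, a, acc, _ in result.folds if a == algo}
            y = np.array([accs[s] for s in fold_order])
            pooled_x.append(vals)
            pooled_y.append(y)
            try:
                r, p = spearman(vals, y)
                out[key][algo] = {"r": r, "p": p, "n": len(y),
                                  "significant": bool(p < alpha_adj)}
            except (DegenerateDataError, InsufficientDataError):
                out[key][algo] = {"r": None, "p": None, "n": len(y),
                                  "significant": False}
        try:
            r, p = spearman(np.concatenate(pooled_x), np.concatenate(pooled_y))
            out[key]["overall"] = {
                "r": r, "p": p,
                "n": sum(len(y) for y in pooled_y),
                "significant": bool(p < alpha_adj),
            }
        except (DegenerateDataError, InsufficientDataError):
            out[key]["overall"] = {"r": None, "p": None, "n": 0,
                                   "significant": False}
    return out
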