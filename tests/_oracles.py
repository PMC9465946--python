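"""Independent brute-force oracles used to check the package's fast paths.

Everything here is written as plain double loops over the defining formulas,
deliberately ignoring vectorization and any code path of the package under
test.
"""

from __future__ import annotations

import math

import numpy as np


def covariance_loops(X: np.ndarray) -> np.ndarray:
    """Unbiased sample covariance as an explicit double loop."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    mean = [sum(X[i, j] for i in range(n)) / n for j in range(d)]
    C = np.zeros((d, d))
    for a in range(d):
        for b in range(d):
            s = 0.0
            for i in range(n):
                s += (X[i, a] - mean[a]) * (X[i, b] - mean[b])
            C[a, b] = s / (n - 1)
    return C


def mmd2_quadratic_loops(Xs, Xt, gamma: float) -> float:
    """Three-term V-statistic evaluated pair by pair."""
    def k(a, b):
        return math.exp(-gamma * sum((ai - bi) ** 2 for ai, bi in zip(a, b)))

    ns, nt = len(Xs), len(Xt)
    ss = sum(k(Xs[i], Xs[j]) for i in range(ns) for j in range(ns)) / ns**2
    tt = sum(k(Xt[i], Xt[j]) for i in range(nt) for j in range(nt)) / nt**2
    st = sum(k(Xs[i], Xt[j]) for i in range(ns) for j in range(nt)) / (ns * nt)
    return ss + tt - 2.0 * st


def h_score_loops(phi: np.ndarray, y: np.ndarray) -> float:
    """tr(pinv(cov_total) @ cov_between) with explicitly looped covariances."""
    phi = np.asarray(phi, dtype=float)
    y = np.asarray(y)
    n, d = phi.shape
    mu = phi.mean(axis=0)
    total = np.zeros((d, d))
    for i in range(n):
        diff = phi[i] - mu
        total += np.outer(diff, diff)
    total /= n
    between = np.zeros((d, d))
    for c in np.unique(y):
        idx = [i for i in range(n) if y[i] == c]
        mc = phi[idx].mean(axis=0)
        between += (len(idx) / n) * np.outer(mc - mu, mc - mu)
    return float(np.trace(np.linalg.pinv(total) @ between))


def hypothesis_margin_loops(Xs: np.ndarray, Xt: np.ndarray) -> float:
    """Mean of (||x - nearmiss|| - ||x - nearhit||)/2 over the union."""
    Xs = [np.asarray(x, dtype=float) for x in Xs]
    Xt = [np.asarray(x, dtype=float) for x in Xt]

    def dist(a, b):
        return float(np.sqrt(np.sum((a - b) ** 2)))

    margins = []
    for own, other in ((Xs, Xt), (Xt, Xs)):
        for i, x in enumerate(own):
            hit = min(dist(x, own[j]) for j in range(len(own)) if j != i)
            miss = min(dist(x, o) for o in other)
            margins.append(0.5 * (miss - hit))
    return float(np.mean(margins))


def silhouette_cross_loops(Xs: np.ndarray, Xt: np.ndarray) -> float:
    """Mean of (B - A)/max(A, B) over the union, loops only."""
    Xs = [np.asarray(x, dtype=float) for x in Xs]
    Xt = [np.asarray(x, dtype=float) for x in Xt]

    def dist(a, b):
        return float(np.sqrt(np.sum((a - b) ** 2)))

    vals = []
    for own, other in ((Xs, Xt), (Xt, Xs)):
        for i, x in enumerate(own):
            A = np.mean([dist(x, own[j]) for j in range(len(own)) if j != i])
            B = np.mean([dist(x, o) for o in other])
            m = max(A, B)
            vals.append(0.0 if m == 0 else (B - A) / m)
    return float(np.mean(vals))


def tdas_loops(S_aligned: np.ndarray, T_proj: np.ndarray, eps: float) -> float:
    """Average count of target rows with dot-product similarity >= eps."""
    counts = []
    for s in S_aligned:
        c = 0
        for t in T_proj:
            if float(np.dot(s, t)) >= eps:
                c += 1
        counts.append(c)
    return float(np.mean(counts))


def spearman_loops(x: np.ndarray, y: np.ndarray) -> float:
    """Average-rank transform followed by a hand-rolled Pearson r."""

    def ranks(v):
        v = list(map(float, v))
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)) * math.sqrt(
        sum((b - my) ** 2 for b in ry)
    )
    return num / den


def cohens_kappa_loops(y_true, y_pred) -> float:
    """kappa from explicit confusion-matrix sums."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    n = len(y_true)
    labels = sorted(set(y_true) | set(y_pred))
    p_o = sum(1 for a, b in zip(y_true, y_pred) if a == b) / n
    p_e = 0.0
    for c in labels:
        p_e += (y_true.count(c) / n) * (y_pred.count(c) / n)
    return (p_o - p_e) / (1.0 - p_e)
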