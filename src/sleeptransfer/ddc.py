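"""Reference trainer for Deep Domain Confusion (DDC).

DDC trains a network simultaneously on labeled source and target samples
while penalizing the maximum mean discrepancy between source and target
activations at a chosen layer, pushing the network toward domain-invariant
features.  The trainer here is a compact one-hidden-layer network (tanh
hidden layer, softmax output) written directly in numpy with manual
backpropagation and an Adam optimizer; the MMD penalty is applied to the
hidden layer — the analogue of penalizing the last feature-extraction layer
of a deep model.

Within each batch the penalty uses the linear-time MMD estimator on a
seeded per-batch shuffle (its unbiasedness derivation assumes i.i.d.
batches), with an analytic gradient of the RBF kernel terms with respect to
the activations.  The kernel bandwidth follows the median heuristic,
recomputed once per epoch from a fixed-size subsample of pooled hidden
activations so it tracks the evolving activation scale deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UsageError
from .features import FeatureTable
from .mmd import KernelSpec, median_heuristic, mmd2_quadratic


@dataclass
class DDCModel:
    """Trained one-hidden-layer network plus its per-epoch loss traces."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    classes: np.ndarray
    task_loss_trace: list = field(default_factory=list)
    mmd_trace: list = field(default_factory=list)
    final_mmd2: float = 0.0
    mmd_weight: float = 0.0

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(np.asarray(X, dtype=float) @ self.W1 + self.b1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.hidden(X) @ self.W2 + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _linear_mmd_with_grad(
    Hs: np.ndarray, Ht: np.ndarray, gamma: float, rng: np.random.Generator
) -> tuple[float, np.ndarray, np.ndarray]:
    """Linear-time MMD^2 on a shuffled batch pair and its gradient.

    Returns ``(mmd2, dHs, dHt)`` where the gradients are with respect to the
    hidden activations (rows not drawn into a quadruple get zero gradient).
    """
    n = min(Hs.shape[0], Ht.shape[0])
    n -= n % 2
    if n < 2:
        return 0.0, np.zeros_like(Hs), np.zeros_like(Ht)
    ps = rng.permutation(Hs.shape[0])[:n]
    pt = rng.permutation(Ht.shape[0])[:n]
    m = n // 2
    dHs = np.zeros_like(Hs)
    dHt = np.zeros_like(Ht)
    total = 0.0

    def accum(A, ia, dA, B, ib, dB, sign):
        nonlocal total
        diff = A[ia] - B[ib]
        k = np.exp(-gamma * np.sum(diff**2, axis=1))
        total += sign * k.sum()
        g = sign * (-2.0 * gamma) * diff * k[:, None] / m
        np.add.at(dA, ia, g)
        np.add.at(dB, ib, -g)

    s1, s2 = ps[0::2], ps[1::2]
    t1, t2 = pt[0::2], pt[1::2]
    accum(Hs, s1, dHs, Hs, s2, dHs, +1.0)
    accum(Ht, t1, dHt, Ht, t2, dHt, +1.0)
    accum(Hs, s1, dHs, Ht, t2, dHt, -1.0)
    accum(Ht, t1, dHt, Hs, s2, dHs, -1.0)
    return total / m, dHs, dHt


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def ddc_reference_train(
    Xs: FeatureTable,
    ys: np.ndarray | None = None,
    Xt: FeatureTable | None = None,
    yt_train: np.ndarray | None = None,
    hidden_width: int = 16,
    mmd_weight: float = 1.0,
    epochs: int = 30,
    batch_size: int = 32,
    lr: float = 0.001,
    l2: float = 10**-6.9,
    seed: int = 0,
) -> DDCModel:
    """Train the reference network on source + target with an MMD penalty.

    Each epoch draws paired source/target batches (seeded shuffles of both
    domains); the loss on a batch pair is the mean cross-entropy over the
    pooled labeled samples plus ``mmd_weight`` times the linear-time MMD
    between the source and target hidden activations, plus an L2 penalty.
    With ``mmd_weight = 0`` the domain-confusion machinery is skipped
    entirely and the run is plain supervised training on the pooled data.

    Returns the model with per-epoch task-loss and MMD traces; the reported
    ``final_mmd2`` is the quadratic-estimator MMD between all source and all
    target hidden activations after the last epoch.
    """
    if Xt is None or Xt.n == 0:
        raise UsageError("DDC requires a nonempty target training split")
    if mmd_weight < 0:
        raise ParameterError("mmd_weight must be >= 0")
    ys = Xs.labels if ys is None else np.asarray(ys)
    yt = Xt.labels if yt_train is None else np.asarray(yt_train)
    classes = np.unique(np.concatenate([ys, yt]))
    K = classes.size
    d = Xs.d
    cs = np.searchsorted(classes, ys)
    ct = np.searchsorted(classes, yt)
    rng = np.random.default_rng(seed)
    mmd_rng = np.random.default_rng(rng.integers(2**31))

    W1 = rng.normal(0, 1.0 / np.sqrt(d), size=(d, hidden_width))
    b1 = np.zeros(hidden_width)
    W2 = rng.normal(0, 1.0 / np.sqrt(hidden_width), size=(hidden_width, K))
    b2 = np.zeros(K)
    params = [W1, b1, W2, b2]
    opt = _Adam(params, lr)

    Fs, Ft = Xs.features, Xt.features
    ns, nt = Fs.shape[0], Ft.shape[0]
    n_batches = max(1, min(ns, nt) // batch_size)
    task_trace, mmd_trace = [], []

    # bandwidth subsample indices are fixed across epochs for determinism
    pool_idx_s = rng.permutation(ns)[:128]
    pool_idx_t = rng.permutation(nt)[:128]

    for _ in range(epochs):
        perm_s = rng.permutation(ns)
        perm_t = rng.permutation(nt)
        gamma = None
        if mmd_weight > 0:
            H_pool = np.tanh(
                np.vstack([Fs[pool_idx_s], Ft[pool_idx_t]]) @ W1 + b1
            )
            try:
                gamma = median_heuristic(H_pool).gamma
            except Exception:
                gamma = 1.0
        ep_task, ep_mmd = 0.0, 0.0
        for bi in range(n_batches):
            bs = perm_s[bi * batch_size : (bi + 1) * batch_size]
            bt = perm_t[bi * batch_size : (bi + 1) * batch_size]
            Xb = np.vstack([Fs[bs], Ft[bt]])
            yb = np.concatenate([cs[bs], ct[bt]])
            nb = Xb.shape[0]
            A1 = Xb @ W1 + b1
            H = np.tanh(A1)
            logits = H @ W2 + b2
            logits -= logits.max(axis=1, keepdims=True)
            expz = np.exp(logits)
            P = expz / expz.sum(axis=1, keepdims=True)
            task = float(
                -np.mean(np.log(np.clip(P[np.arange(nb), yb], 1e-300, None)))
            )
            dlogits = P.copy()
            dlogits[np.arange(nb), yb] -= 1.0
            dlogits /= nb
            gW2 = H.T @ dlogits + 2 * l2 * W2
            gb2 = dlogits.sum(axis=0)
            dH = dlogits @ W2.T
            mmd_val = 0.0
            if mmd_weight > 0 and gamma is not None:
                nsb = len(bs)
                mmd_val, dHs, dHt = _linear_mmd_with_grad(
                    H[:nsb], H[nsb:], gamma, mmd_rng
                )
                dH = dH + mmd_weight * np.vstack([dHs, dHt])
            dA1 = dH * (1.0 - H**2)
            gW1 = Xb.T @ dA1 + 2 * l2 * W1
            gb1 = dA1.sum(axis=0)
            opt.step(params, [gW1, gb1, gW2, gb2])
            ep_task += task
            ep_mmd += mmd_val
        task_trace.append(ep_task / n_batches)
        mmd_trace.append(ep_mmd / n_batches)

    model = DDCModel(
        W1=W1, b1=b1, W2=W2, b2=b2, classes=classes,
        task_loss_trace=task_trace, mmd_trace=mmd_trace,
        mmd_weight=mmd_weight,
    )
    Hs_all, Ht_all = model.hidden(Fs), model.hidden(Ft)
    try:
        spec = median_heuristic(np.vstack([Hs_all, Ht_all]))
        model.final_mmd2 = mmd2_quadratic(Hs_all, Ht_all, spec).mmd2
    except Exception:
        model.final_mmd2 = 0.0
    return model
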