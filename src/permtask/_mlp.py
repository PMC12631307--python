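"""Minimal feed-forward network with a masked multitask squared loss.

Two ReLU hidden layers feed a readout with a *shared* linear component (one
scalar added to every task) plus *task-specific* linear offsets, initialized
at zero and L2-penalized.  On per-task standardized targets the shared
component absorbs whatever the tasks have in common, so a task that never
receives a gradient (no observed labels) still inherits the shared signal —
the mechanism behind cross-task transfer to label-free endpoints.

Optimization is Adam on minibatches with early stopping on a held-out slice.
Everything is plain float32 numpy; no autodiff framework is needed at this
scale.
"""

from __future__ import annotations

import numpy as np


def masked_mse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over observed cells only (0 for an empty mask)."""
    m = mask.astype(bool)
    if pred.shape != target.shape or pred.shape != m.shape:
        raise ValueError("pred, target and mask shapes must agree")
    n_obs = int(m.sum())
    if n_obs == 0:
        import warnings

        warnings.warn("masked loss over an empty mask; returning 0.0")
        return 0.0
    diff = np.where(m, pred - target, 0.0)
    return float((diff * diff).sum() / n_obs)


class MaskedMLP:
    def __init__(
        self,
        n_features: int,
        n_tasks: int,
        hidden: tuple[int, int] = (128, 64),
        l2: float = 1e-5,
        l2_task: float = 1e-3,
        lr: float = 1e-3,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        h1, h2 = hidden
        def init(fan_in, shape):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params = {
            "W1": init(n_features, (n_features, h1)),
            "b1": np.zeros(h1, np.float32),
            "W2": init(h1, (h1, h2)),
            "b2": np.zeros(h2, np.float32),
            "ws": init(h2, (h2, 1)),
            "bs": np.zeros(1, np.float32),
            "Wt": np.zeros((h2, n_tasks), np.float32),
            "bt": np.zeros(n_tasks, np.float32),
        }
        self.l2, self.l2_task, self.lr = l2, l2_task, lr
        self._adam = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in self.params.items()}
        self._t = 0

    def forward(self, X: np.ndarray, cache: bool = False):
        p = self.params
        Z1 = X @ p["W1"] + p["b1"]
        H1 = np.maximum(Z1, 0)
        Z2 = H1 @ p["W2"] + p["b2"]
        H2 = np.maximum(Z2, 0)
        out = (H2 @ p["ws"] + p["bs"]) + (H2 @ p["Wt"] + p["bt"])
        if cache:
            return out, (X, Z1, H1, Z2, H2)
        return out

    def _grads(self, X, Y, M):
        p = self.params
        out, (X, Z1, H1, Z2, H2) = self.forward(X, cache=True)
        n_obs = max(int(M.sum()), 1)
        dOut = (2.0 / n_obs) * np.where(M, out - Y, 0.0).astype(np.float32)
        g = {}
        g["Wt"] = H2.T @ dOut + 2 * self.l2_task * p["Wt"]
        g["bt"] = dOut.sum(0) + 2 * self.l2_task * p["bt"]
        dShared = dOut.sum(1, keepdims=True)
        g["ws"] = H2.T @ dShared + 2 * self.l2 * p["ws"]
        g["bs"] = dShared.sum(0)
        dH2 = dOut @ p["Wt"].T + dShared @ p["ws"].T
        dZ2 = dH2 * (Z2 > 0)
        g["W2"] = H1.T @ dZ2 + 2 * self.l2 * p["W2"]
        g["b2"] = dZ2.sum(0)
        dZ1 = (dZ2 @ p["W2"].T) * (Z1 > 0)
        g["W1"] = X.T @ dZ1 + 2 * self.l2 * p["W1"]
        g["b1"] = dZ1.sum(0)
        return g

    def _adam_step(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        for k, grad in grads.items():
            m, v = self._adam[k]
            m[:] = beta1 * m + (1 - beta1) * grad
            v[:] = beta2 * v + (1 - beta2) * grad * grad
            mhat = m / (1 - beta1 ** self._t)
            vhat = v / (1 - beta2 ** self._t)
            self.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        M: np.ndarray,
        X_val: np.ndarray | None = None,
        Y_val: np.ndarray | None = None,
        M_val: np.ndarray | None = None,
        max_epochs: int = 200,
        batch_size: int = 256,
        patience: int = 20,
        seed: int = 0,
    ) -> dict:
        """Train with early stopping; returns a history dict."""
        X = np.ascontiguousarray(X, np.float32)
        Y = np.ascontiguousarray(Y, np.float32)
        M = np.ascontiguousarray(M, np.float32)
        rng = np.random.default_rng(seed)
        has_val = X_val is not None and len(X_val) > 0 and M_val.sum() > 0
        best_loss, best_params, best_epoch, wait = np.inf, None, 0, 0
        history = {"train": [], "val": []}
        n = len(X)
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                if M[idx].sum() == 0:
                    continue
                self._adam_step(self._grads(X[idx], Y[idx], M[idx]))
            history["train"].append(masked_mse(self.forward(X), Y, M))
            if has_val:
                val = masked_mse(self.forward(X_val.astype(np.float32)), Y_val, M_val)
                history["val"].append(val)
                if val < best_loss - 1e-6:
                    best_loss, best_epoch, wait = val, epoch, 0
                    best_params = {k: v.copy() for k, v in self.params.items()}
                else:
                    wait += 1
                    if wait >= patience:
                        break
        if best_params is not None:
            self.params = best_params
        history["best_epoch"] = best_epoch if has_val else max_epochs - 1
        return history
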