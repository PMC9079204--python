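"""Adam optimiser, plateau learning-rate schedule and the weighted loss."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, net, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.net = net
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.parameters()]
        self.v = [np.zeros_like(p) for p, _ in net.parameters()]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(self.net.parameters(), self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Multiply the LR by ``factor`` after ``patience`` epochs without a new
    best monitored value; floor at ``min_lr``."""

    def __init__(self, factor=0.1, patience=2, min_lr=1e-7):
        self.factor = float(factor)
        self.patience = int(patience)
        self.min_lr = float(min_lr)
        self.best = np.inf
        self.wait = 0

    def update(self, monitored: float, lr: float) -> float:
        if monitored < self.best - 1e-12:
            self.best = monitored
            self.wait = 0
            return lr
        self.wait += 1
        if self.wait >= self.patience:
            self.wait = 0
            return max(lr * self.factor, self.min_lr)
        return lr


def weighted_sparse_ce(probs: np.ndarray, y: np.ndarray, sample_weight=None):
    """Class-weighted sparse categorical cross-entropy on probabilities.

    Returns ``(loss, dprobs)`` where loss is the batch mean of
    ``w_i * -log p_i[y_i]`` and ``dprobs`` is its gradient w.r.t. the
    probability outputs (to be fed through the softmax layer's backward).
    """
    n = len(y)
    p = np.clip(probs[np.arange(n), y], 1e-12, None)
    w = np.ones(n, dtype=probs.dtype) if sample_weight is None else sample_weight
    loss = float(np.mean(w * -np.log(p)))
    dprobs = np.zeros_like(probs)
    dprobs[np.arange(n), y] = -w / (p * n)
    return loss, dprobs
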