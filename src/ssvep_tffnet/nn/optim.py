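"""Optimisation: Adam with L2 regularisation and the cross-entropy loss."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor

__all__ = ["Adam", "cross_entropy"]


class Adam:
    """Adam with bias correction; ``weight_decay`` adds an L2 term to the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` given raw ``logits`` (N, U)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = logits.data.shape[0]
    loss_val = -logp[np.arange(n), labels].mean()
    out = Tensor(np.asarray(loss_val, dtype=logits.data.dtype), parents=(logits,))

    def bwd(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accum((g * p / n).astype(logits.data.dtype))

    out._backward = bwd
    return out
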