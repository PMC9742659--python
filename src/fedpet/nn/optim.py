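"""First-order optimizers over flat parameter vectors.

Adam follows Kingma & Ba with bias correction; SGD is plain.  Weight decay is
the caller's responsibility (the training engine folds the L2 penalty into
the gradient), so either optimizer sees the full objective gradient.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam", "make_optimizer"]


class SGD:
    def __init__(self, learning_rate: float):
        self.lr = float(learning_rate)

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        return theta - self.lr * grad


class Adam:
    def __init__(self, learning_rate: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = float(learning_rate)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = None
        self.v = None
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(theta)
            self.v = np.zeros_like(theta)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad * grad
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, learning_rate: float):
    name = name.lower()
    if name == "sgd":
        return SGD(learning_rate)
    if name == "adam":
        return Adam(learning_rate)
    raise ValueError(f"unknown optimizer {name!r}")
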