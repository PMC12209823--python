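"""Minimal NumPy neural-network core: MLP forward/backward and AdamW.

Written explicitly (no autodiff framework) so the joint attention-MIL +
MLP trainer can run on a plain CPU stack.  Gradients are exact and checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def init_mlp(
    dims: tuple[int, ...],
    seed: int = 0,
    zero_final: bool = True,
    dtype=np.float64,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Layer weights [(W, b), ...] for dims like (in, 1024, 512, 256, out).

    Hidden layers use fan-in-scaled uniform init; the final classification
    layer is zero-initialized by default so an untrained model predicts the
    uniform distribution exactly and early training signal is not swamped
    by init noise (see the methods note).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x91F]))
    layers = []
    for i in range(len(dims) - 1):
        fan_in, fan_out = dims[i], dims[i + 1]
        last = i == len(dims) - 2
        if last and zero_final:
            W = np.zeros((fan_out, fan_in), dtype=dtype)
        else:
            lim = 1.0 / np.sqrt(fan_in)
            W = rng.uniform(-lim, lim, size=(fan_out, fan_in)).astype(dtype)
        layers.append((W, np.zeros(fan_out, dtype=dtype)))
    return layers


def mlp_forward(layers, X: np.ndarray, return_cache: bool = False):
    """ReLU MLP logits for X (n, d_in); returns (logits[, cache])."""
    X = np.atleast_2d(np.asarray(X))
    acts = [X]
    a = X
    for i, (W, b) in enumerate(layers):
        z = a @ W.T + b
        a = z if i == len(layers) - 1 else np.maximum(z, 0.0)
        acts.append(a)
    return (acts[-1], acts) if return_cache else acts[-1]


def mlp_backward(layers, acts, dlogits: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Gradients [(dW, db), ...] plus input gradient via the returned dX.

    Returns (grads, dX); dX is needed when an aggregator sits below the MLP.
    """
    grads: list = [None] * len(layers)
    delta = np.atleast_2d(dlogits)
    for i in range(len(layers) - 1, -1, -1):
        W, _ = layers[i]
        a_prev = acts[i]
        grads[i] = (delta.T @ a_prev, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ W) * (acts[i] > 0)
        else:
            delta = delta @ W
    return grads, delta


def softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over rows and its gradient wrt logits.

    ``y`` holds integer class indices.
    """
    logits = np.atleast_2d(logits)
    n = logits.shape[0]
    p = softmax_rows(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class AdamW:
    """AdamW (decoupled weight decay) over a dict of parameter arrays."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient for parameter {k!r}")
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * self.weight_decay * p  # decoupled decay
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
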