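"""Minimal NumPy neural-network primitives used by the encoder and heads.

Implements exactly what the affinity models need -- dense ReLU networks
with inverted dropout, analytic backward passes, and Adam -- operating on
single samples (sequence lengths vary pair to pair, so batching happens by
gradient accumulation in the training loop).  All parameters live in plain
``numpy`` arrays inside nested dicts; :func:`flatten_params` fixes a
deterministic ordering for the optimizer and for checkpoint I/O.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = [
    "init_mlp",
    "mlp_forward",
    "mlp_backward",
    "Adam",
    "flatten_params",
    "assign_params",
    "copy_params",
    "params_checksum",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # piecewise form avoids overflow in exp for large |x|
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_mlp(sizes: list[int], rng: np.random.Generator) -> list[dict]:
    """He-initialized dense layers; ``sizes`` includes input and output."""
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        layers.append(
            {
                "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_out, fan_in)),
                "b": np.zeros(fan_out),
            }
        )
    return layers


def mlp_forward(
    layers: list[dict],
    x: np.ndarray,
    dropout: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, dict]:
    """ReLU MLP; dropout (inverted) on hidden activations when ``rng`` given."""
    h = np.asarray(x, dtype=np.float64)
    inputs, masks = [], []
    n = len(layers)
    for k, layer in enumerate(layers):
        inputs.append(h)
        z = layer["W"] @ h + layer["b"]
        if k < n - 1:
            h = np.maximum(z, 0.0)
            if dropout > 0.0 and rng is not None:
                mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                h = h * mask
            else:
                mask = None
            masks.append((z, mask))
        else:
            h = z
    return h, {"inputs": inputs, "masks": masks}


def mlp_backward(
    layers: list[dict], cache: dict, dy: np.ndarray
) -> tuple[list[dict], np.ndarray]:
    """Gradients of all layers plus the gradient w.r.t. the input."""
    grads = [None] * len(layers)
    dh = np.asarray(dy, dtype=np.float64)
    for k in range(len(layers) - 1, -1, -1):
        if k < len(layers) - 1:
            z, mask = cache["masks"][k]
            if mask is not None:
                dh = dh * mask
            dh = dh * (z > 0.0)
        x_in = cache["inputs"][k]
        grads[k] = {"W": np.outer(dh, x_in), "b": dh.copy()}
        dh = layers[k]["W"].T @ dh
    return grads, dh


def flatten_params(params) -> list[np.ndarray]:
    """Deterministic flat view of a nested dict/list/array parameter tree."""
    out: list[np.ndarray] = []
    _flatten(params, out)
    return out


def _flatten(node, out: list[np.ndarray]) -> None:
    if isinstance(node, np.ndarray):
        out.append(node)
    elif isinstance(node, dict):
        for key in sorted(node):
            _flatten(node[key], out)
    elif isinstance(node, (list, tuple)):
        for item in node:
            _flatten(item, out)
    elif node is None:
        pass
    else:
        raise TypeError(f"unsupported parameter node type {type(node)!r}")


def copy_params(params):
    if isinstance(params, np.ndarray):
        return params.copy()
    if isinstance(params, dict):
        return {k: copy_params(v) for k, v in params.items()}
    if isinstance(params, (list, tuple)):
        return type(params)(copy_params(v) for v in params)
    return params


def assign_params(dst, src) -> None:
    """Copy values of ``src`` into the arrays of ``dst`` in place."""
    for d, s in zip(flatten_params(dst), flatten_params(src), strict=True):
        d[...] = s


def params_checksum(params) -> float:
    """Cheap bitwise-sensitive fingerprint (for freeze assertions)."""
    return float(sum(np.abs(a).sum() + a.view(np.uint8).sum() for a in flatten_params(params)))


class Adam:
    """Adaptive-moment optimizer over a flat list of parameter arrays."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay > 0.0:  # decoupled (AdamW-style)
                p -= self.lr * self.weight_decay * p
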