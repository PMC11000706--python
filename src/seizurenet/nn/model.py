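"""Sequential network container, Adam optimizer and the training loop."""
from __future__ import annotations

import numpy as np

from .layers import Layer


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class Adam:
    """Adam optimizer with the conventional defaults (lr 1e-3, beta1 0.9,
    beta2 0.999, eps 1e-7)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.beta2 ** self.t) / (
            1.0 - self.beta1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)


class Sequential:
    """Ordered stack of layers trained with softmax cross-entropy.

    The final layer must be a softmax ``Dense``; ``fit`` fuses the
    softmax/cross-entropy gradient (``p - y``) at the output.
    """

    def __init__(self, layers: list[Layer]):
        if not layers:
            raise ValueError("a model needs at least one layer")
        self.layers = layers

    # -- introspection -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def count_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def layer_names(self) -> list[str]:
        return [layer.name for layer in self.layers]

    def summary(self) -> str:
        lines = [f"{i:>2}  {layer.name:<14} params={layer.n_params()}"
                 for i, layer in enumerate(self.layers)]
        lines.append(f"total trainable parameters: {self.count_params()}")
        return "\n".join(lines)

    # -- inference -----------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, training=training)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [self.forward(x[i:i + batch_size].astype(np.float32))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        # argmax breaks ties toward the lowest class index
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- training ------------------------------------------------------
    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def fit(self, x: np.ndarray, y_onehot: np.ndarray, epochs: int,
            batch_size: int, rng: np.random.Generator,
            lr: float = 1e-3, verbose: bool = False) -> list[float]:
        """Train with Adam on softmax cross-entropy; returns per-epoch losses.

        Raises :class:`TrainingDivergedError` if the loss turns non-finite.
        """
        x = x.astype(np.float32, copy=False)
        y_onehot = y_onehot.astype(np.float32, copy=False)
        n = len(x)
        opt = Adam(self.params, lr=lr)
        history: list[float] = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = x[idx], y_onehot[idx]
                p = self.forward(xb, training=True)
                p_clip = np.clip(p, 1e-7, 1.0)
                loss = -float((yb * np.log(p_clip)).sum()) / len(idx)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}")
                total += loss * len(idx)
                self.backward((p - yb) / np.float32(len(idx)))
                opt.step(self.grads)
            history.append(total / n)
            if verbose:
                print(f"epoch {epoch + 1}/{epochs} loss {history[-1]:.4f}")
        return history
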