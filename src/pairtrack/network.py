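"""Compact fully connected embedding network, implemented natively in numpy.

The network maps a flattened L x L grayscale crop to a point in R^M
(M = 8 by default).  Architecture: ``input -> hidden ReLU layers -> linear
head``.  Gradients are hand-derived (straightforward dense backprop) and
parameters are updated with Adam.  At the 20-100 px image scale the
identity signal is a textured appearance pattern, which a dense network
separates comfortably; the class is deliberately simple, deterministic
given a seed, and fast on a single CPU core.

Inference is deterministic: repeated calls to :meth:`embed` on the same
inputs return identical outputs.
"""

from __future__ import annotations

import json

import numpy as np

from .errors import InvalidInputError

__all__ = ["EmbeddingNetwork"]


class EmbeddingNetwork:
    """Dense ReLU network ``input_dim -> hidden... -> output_dim``."""

    def __init__(
        self,
        input_side: int,
        output_dim: int = 8,
        hidden_sizes: tuple[int, ...] = (128, 64),
        learning_rate: float = 1e-3,
        seed: int = 0,
    ) -> None:
        self.input_side = int(input_side)
        self.input_dim = self.input_side * self.input_side
        self.output_dim = int(output_dim)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.learning_rate = float(learning_rate)
        self.seed = int(seed)

        rng = np.random.default_rng(seed)
        sizes = (self.input_dim, *self.hidden_sizes, self.output_dim)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for ReLU layers
            self.weights.append(
                (rng.standard_normal((fan_in, fan_out)) * scale).astype(np.float32)
            )
            self.biases.append(np.zeros(fan_out, dtype=np.float32))

        # Adam state
        self._t = 0
        self._mw = [np.zeros_like(w) for w in self.weights]
        self._vw = [np.zeros_like(w) for w in self.weights]
        self._mb = [np.zeros_like(b) for b in self.biases]
        self._vb = [np.zeros_like(b) for b in self.biases]

    # --- forward / backward ---------------------------------------------

    def _flatten(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 2:
            images = images[None]
        if images.ndim != 3 or images.shape[1:] != (self.input_side, self.input_side):
            raise InvalidInputError(
                f"expected crops of shape ({self.input_side}, {self.input_side}), "
                f"got {images.shape[1:] if images.ndim == 3 else images.shape}"
            )
        return images.reshape(images.shape[0], -1)

    def forward(self, images: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Embeddings plus per-layer activations (for backprop)."""
        a = self._flatten(images)
        activations = [a]
        n_layers = len(self.weights)
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ w + b
            if k < n_layers - 1:
                a = np.maximum(a, 0.0)
            activations.append(a)
        return activations[-1], activations

    def embed(self, images: np.ndarray) -> np.ndarray:
        """Map images to points in R^M; order-preserving and deterministic."""
        out, _ = self.forward(images)
        return out

    def backward(self, activations: list[np.ndarray], grad_out: np.ndarray):
        """Gradients of a scalar loss wrt parameters given d(loss)/d(output)."""
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = grad_out.astype(np.float32)
        for k in range(len(self.weights) - 1, -1, -1):
            a_in = activations[k]
            grads_w[k] = a_in.T @ delta
            grads_b[k] = delta.sum(axis=0)
            if k > 0:
                delta = delta @ self.weights[k].T
                delta *= (activations[k] > 0)  # ReLU mask
        return grads_w, grads_b

    def adam_step(self, grads_w, grads_b, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._t += 1
        lr = self.learning_rate
        t = self._t
        for k in range(len(self.weights)):
            for g, p, m, v in (
                (grads_w[k], self.weights[k], self._mw[k], self._vw[k]),
                (grads_b[k], self.biases[k], self._mb[k], self._vb[k]),
            ):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * np.square(g)
                m_hat = m / (1 - beta1**t)
                v_hat = v / (1 - beta2**t)
                p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # --- serialization ---------------------------------------------------

    def save(self, path) -> None:
        header = json.dumps(
            {
                "input_side": self.input_side,
                "output_dim": self.output_dim,
                "hidden_sizes": list(self.hidden_sizes),
                "learning_rate": self.learning_rate,
                "seed": self.seed,
            }
        )
        arrays = {"__header__": np.frombuffer(header.encode(), dtype=np.uint8)}
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{k}"] = w
            arrays[f"b{k}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "EmbeddingNetwork":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            net = cls(
                input_side=header["input_side"],
                output_dim=header["output_dim"],
                hidden_sizes=tuple(header["hidden_sizes"]),
                learning_rate=header["learning_rate"],
                seed=header["seed"],
            )
            for k in range(len(net.weights)):
                net.weights[k] = data[f"w{k}"]
                net.biases[k] = data[f"b{k}"]
        return net
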