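"""Minimal feed-forward network engine with hand-written backpropagation.

Both networks in this package are small multilayer perceptrons (4 layers in
the reference configurations) trained full-batch with custom scalar losses,
so a compact numpy implementation with analytic gradients is sufficient.
Gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError


def _relu(z):
    return np.maximum(z, 0.0)


def _drelu(z):
    return (z > 0).astype(z.dtype)


def _sigmoid(z):
    return 0.5 * (np.tanh(0.5 * z) + 1.0)


def _dsigmoid(z):
    s = _sigmoid(z)
    return s * (1.0 - s)


def _dtanh(z):
    return 1.0 - np.tanh(z) ** 2


_ACTIVATIONS = {
    "relu": (_relu, _drelu),
    "sigmoid": (_sigmoid, _dsigmoid),
    "tanh": (np.tanh, _dtanh),
}


class MLP:
    """Fully connected network mapping (n, p) inputs to a scalar per row.

    ``layer_widths`` lists every layer's width and must end in 1 (the scalar
    output layer, which is linear). Hidden layers share one activation.
    Inverted dropout can be attached to a single hidden layer (1-based index
    ``dropout_layer``), so inference needs no rescaling and is deterministic.
    Weights use Xavier (Glorot) uniform initialization.
    """

    def __init__(
        self,
        input_dim: int,
        layer_widths: tuple[int, ...],
        activation: str = "relu",
        dropout_layer: int = 3,
        dropout_rate: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        if not layer_widths or layer_widths[-1] != 1:
            raise ConfigurationError("layer_widths must end in the scalar output width 1")
        if activation not in _ACTIVATIONS:
            raise ConfigurationError(f"unknown activation {activation!r}")
        if not 0.0 <= dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        rng = rng or np.random.default_rng()
        self.activation = activation
        self.dropout_layer = dropout_layer
        self.dropout_rate = dropout_rate
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        dims = [input_dim, *layer_widths]
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def state_hash(self) -> int:
        """Hash of all parameter bytes; used to assert freeze contracts."""
        h = 0
        for arr in self.parameters():
            h ^= hash(arr.tobytes())
        return h

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Return per-row scalar outputs and the cache needed for backward."""
        act, _ = _ACTIVATIONS[self.activation]
        a = np.asarray(X, dtype=float)
        zs, acts, masks = [], [a], []
        for l, (W, b) in enumerate(zip(self.weights, self.biases), start=1):
            z = a @ W + b
            zs.append(z)
            if l < self.n_layers:
                a = act(z)
                if train and self.dropout_rate > 0 and l == self.dropout_layer:
                    mask = (rng.uniform(size=a.shape) >= self.dropout_rate)
                    a = a * mask / (1.0 - self.dropout_rate)
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                a = z
            acts.append(a)
        cache = (zs, acts, masks)
        return a[:, 0], cache

    def backward(self, cache, dout: np.ndarray):
        """Backpropagate dL/d(output) through the cached forward pass.

        Returns (weight grads, bias grads, dL/dX).
        """
        _, dact = _ACTIVATIONS[self.activation]
        zs, acts, masks = cache
        delta = np.asarray(dout, dtype=float)[:, None]
        gW = [None] * self.n_layers
        gb = [None] * self.n_layers
        for l in range(self.n_layers - 1, -1, -1):
            gW[l] = acts[l].T @ delta
            gb[l] = delta.sum(axis=0)
            if l > 0:
                delta = delta @ self.weights[l].T
                mask = masks[l - 1]
                if mask is not None:
                    delta = delta * mask / (1.0 - self.dropout_rate)
                delta = delta * dact(zs[l - 1])
        dX = delta @ self.weights[0].T if self.n_layers else delta
        return gW, gb, dX

    def output_and_hidden_grad(self, X: np.ndarray, layer: int = 1):
        """Outputs, activations of a hidden ``layer`` (1-based), and the
        gradient of each row's output w.r.t. those activations (inference
        mode; used by Grad-CAM)."""
        _, dact = _ACTIVATIONS[self.activation]
        out, (zs, acts, _) = self.forward(X, train=False)
        delta = np.ones((X.shape[0], 1))
        for l in range(self.n_layers - 1, layer - 1, -1):
            delta = (delta @ self.weights[l].T) * dact(zs[l - 1])
        return out, acts[layer], delta

    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.parameters()])

    def set_flat(self, flat: np.ndarray) -> None:
        i = 0
        for p in self.parameters():
            p[...] = flat[i : i + p.size].reshape(p.shape)
            i += p.size


class Adam:
    """Adam optimizer over an MLP's parameter list."""

    def __init__(self, net: MLP, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        params = net.parameters()
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, gW: list[np.ndarray], gb: list[np.ndarray]) -> None:
        self.t += 1
        grads = gW + gb
        params = self.net.parameters()
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
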