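"""Minimal feed-forward neural-network engine on numpy.

Implements exactly the pieces the encoding networks and the six-layer
classifier need: dense layers, tanh/ReLU/sigmoid activations, inverted
dropout, batch normalization, Adam, and the three loss families used in
training (binary cross-entropy, mean squared error, softmax cross-entropy).
Backpropagation is hand-written and checked against numerical gradients in
the test suite.

All randomness (weight init, batch shuffling, dropout masks) flows through
`numpy.random.Generator` objects supplied by the caller, so training is
bit-reproducible for a fixed seed on a fixed machine.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Tanh",
    "Relu",
    "Sigmoid",
    "Dropout",
    "BatchNorm",
    "Sequential",
    "Adam",
    "bce_loss",
    "mse_loss",
    "softmax",
    "softmax_cross_entropy",
]

_EPS = 1e-7


class Layer:
    """Base class; layers with no parameters inherit the empty defaults."""

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, training):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    """Affine map x @ W + b with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


class Tanh(Layer):
    def forward(self, x, training):
        self._y = np.tanh(x)
        return self._y

    def backward(self, g):
        return g * (1.0 - self._y ** 2)


class Relu(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)


class Sigmoid(Layer):
    def forward(self, x, training):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask


class BatchNorm(Layer):
    """Batch normalization over the feature axis.

    Training uses batch statistics and updates running moments with
    exponential momentum; inference uses the running moments.
    """

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        self._n = x.shape[0]
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        self.dgamma[...] = (g * self._xhat).sum(axis=0)
        self.dbeta[...] = g.sum(axis=0)
        if not self._training:
            return g * self.gamma * self._istd
        n = self._n
        # standard batch-norm backward through the batch statistics
        return (self.gamma * self._istd / n) * (
            n * g - g.sum(axis=0) - self._xhat * (g * self._xhat).sum(axis=0)
        )


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training: bool = False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [p for layer in self.layers for p in layer.grads()]

    # -- persistence ---------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat dict of every parameter and running statistic."""
        out = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                out[f"l{i}_p{j}"] = p
            if isinstance(layer, BatchNorm):
                out[f"l{i}_rm"] = layer.running_mean
                out[f"l{i}_rv"] = layer.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                p[...] = arrays[f"l{i}_p{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(arrays[f"l{i}_rm"])
                layer.running_var = np.asarray(arrays[f"l{i}_rv"])


class Adam:
    """Adam optimizer with the usual bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g ** 2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# losses: each returns (scalar mean loss, gradient wrt the network output)


def bce_loss(pred, target):
    """Per-element binary cross-entropy, averaged; pred in (0,1)."""
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    loss = -(target * np.log(p) + (1 - target) * np.log(1 - p)).mean()
    grad = (p - target) / (p * (1 - p)) / p.size
    return loss, grad

def mse_loss(pred, target):
    diff = pred - target
    return (diff ** 2).mean(), 2.0 * diff / diff.size

def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)

def softmax_cross_entropy(logits, onehot):
    """Categorical cross-entropy on logits; grad is wrt the logits."""
    p = softmax(logits)
    loss = -(onehot * np.log(np.clip(p, _EPS, None))).sum(axis=1).mean()
    grad = (p - onehot) / logits.shape[0]
    return loss, grad


def iterate_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Yield shuffled index batches covering all n samples once."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
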