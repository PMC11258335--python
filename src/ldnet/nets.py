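"""Dense tanh networks with hand-written reverse-mode differentiation.

The networks here are tiny (tens to hundreds of parameters), so a compact
numpy implementation with explicit forward caches and a backward pass is
both fast and dependency-free.  Hidden layers use the hyperbolic tangent;
the output layer is affine.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FCNN", "glorot_init", "tail_compress", "tail_compress_derivative"]


class FCNN:
    """Fully-connected network defined by its layer widths.

    Parameters are stored as lists of weight matrices ``W[l]`` of shape
    (fan_in, fan_out) and bias vectors ``b[l]``.
    """

    def __init__(self, widths):
        widths = [int(w) for w in widths]
        if len(widths) < 2 or any(w < 1 for w in widths):
            raise ValueError("need at least input and output widths, all >= 1")
        self.widths = widths
        self.weights = [np.zeros((widths[l], widths[l + 1])) for l in range(len(widths) - 1)]
        self.biases = [np.zeros(widths[l + 1]) for l in range(len(widths) - 1)]

    # -- parameter vector interface (used by the optimizers) ---------------
    @property
    def n_params(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    def get_params_vector(self) -> np.ndarray:
        return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in zip(self.weights, self.biases)])

    def set_params_vector(self, theta: np.ndarray) -> None:
        i = 0
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[l] = theta[i : i + W.size].reshape(W.shape).copy()
            i += W.size
            self.biases[l] = theta[i : i + b.size].copy()
            i += b.size
        if i != theta.size:
            raise ValueError("parameter vector size mismatch")

    # -- evaluation --------------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        return self.forward_cache(X)[0]

    def forward_cache(self, X: np.ndarray):
        """Evaluate the network, returning (output, cache) for backward()."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        A = X[None, :] if single else X
        if A.shape[1] != self.widths[0]:
            raise ValueError(f"input width {A.shape[1]} != expected {self.widths[0]}")
        activations = [A]
        n_layers = len(self.weights)
        for l in range(n_layers):
            Z = A @ self.weights[l]
            Z += self.biases[l]
            A = np.tanh(Z, out=Z) if l < n_layers - 1 else Z
            activations.append(A)
        out = activations[-1]
        return (out[0] if single else out), activations

    def backward(self, activations, dY: np.ndarray):
        """Reverse pass: returns (dX, grad_weights, grad_biases).

        ``dY`` holds the upstream gradient with respect to the output rows;
        gradients are summed over the batch.
        """
        dY = np.asarray(dY, dtype=float)
        if dY.ndim == 1:
            dY = dY[None, :]
        n_layers = len(self.weights)
        gW = [None] * n_layers
        gb = [None] * n_layers
        delta = dY
        for l in range(n_layers - 1, -1, -1):
            if l < n_layers - 1:  # undo tanh of this layer's output
                a = activations[l + 1]
                delta = delta * (1.0 - a * a)
            gW[l] = activations[l].T @ delta
            gb[l] = delta.sum(axis=0)
            delta = delta @ self.weights[l].T
        return delta, gW, gb


def glorot_init(net: FCNN, seed: int) -> FCNN:
    """Glorot-uniform weights, exactly zero biases; deterministic under seed."""
    rng = np.random.default_rng(seed)
    for l, W in enumerate(net.weights):
        fan_in, fan_out = W.shape
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        net.weights[l] = rng.uniform(-limit, limit, size=W.shape)
        net.biases[l] = np.zeros(W.shape[1])
    return net


def tail_compress(y, beta):
    """Tail-compression layer y -> (y^3 + beta*y) / (1 + beta).

    A strictly increasing odd bijection fixing 0 and +/-1 for every
    ``beta > 0``; used as a final non-trainable layer when an output channel
    has a long-tailed distribution.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    y = np.asarray(y, dtype=float)
    return (y**3 + beta * y) / (1.0 + beta)


def tail_compress_derivative(y, beta):
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    y = np.asarray(y, dtype=float)
    return (3.0 * y**2 + beta) / (1.0 + beta)
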