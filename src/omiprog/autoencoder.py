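"""A fully-connected autoencoder for multiomics integration.

The network is symmetric with an odd number of hidden layers; the middle
(bottleneck) layer is the low-dimensional representation used downstream.
Each hidden block is dense -> tanh -> batch normalization (the batch-norm
layer counters overfitting on wide omics inputs); the output layer is
linear.  Training minimizes mean squared reconstruction error with Adam for
a fixed number of epochs — no early stopping, no validation split.

Implemented directly in NumPy: forward/backward passes, batch-norm
statistics and the Adam update are all explicit, which keeps training
bit-reproducible for a given seed on one machine.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import OmiprogError

__all__ = ["Autoencoder"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class _Dense:
    def __init__(self, rng, n_in, n_out, dtype):
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)

    def forward(self, h):
        self._h = h
        return h @ self.W + self.b

    def backward(self, dz):
        self.dW = self._h.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.W.T

    def params(self):
        return [self.W, self.b]

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _BatchNorm:
    def __init__(self, n, dtype):
        self.gamma = np.ones(n, dtype=dtype)
        self.beta = np.zeros(n, dtype=dtype)
        self.running_mean = np.zeros(n, dtype=dtype)
        self.running_var = np.ones(n, dtype=dtype)

    def forward(self, a, training):
        if training:
            mu = a.mean(axis=0)
            var = a.var(axis=0)
            self.running_mean = (_BN_MOMENTUM * self.running_mean
                                 + (1 - _BN_MOMENTUM) * mu)
            self.running_var = (_BN_MOMENTUM * self.running_var
                                + (1 - _BN_MOMENTUM) * var)
        else:
            mu, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + _BN_EPS)
        self._xhat = (a - mu) * self._istd
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        n = dout.shape[0]
        xhat, istd = self._xhat, self._istd
        self.dgamma = (dout * xhat).sum(axis=0)
        self.dbeta = dout.sum(axis=0)
        dxhat = dout * self.gamma
        return (istd / n) * (n * dxhat - dxhat.sum(axis=0)
                             - xhat * (dxhat * xhat).sum(axis=0))

    def params(self):
        return [self.gamma, self.beta]

    def params_grads(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class Autoencoder(TransformerMixin, BaseEstimator):
    """Symmetric autoencoder; ``transform`` returns bottleneck activations.

    Parameters
    ----------
    hidden_sizes : tuple of int
        Sizes of the hidden layers; must be odd in number, the middle one is
        the bottleneck.  Hidden sizes wider than the input are shrunk to the
        input width with a warning.
    activation : {"tanh"}
        Hidden activation.
    epochs, batch_size, learning_rate
        Adam training schedule (fixed epoch count, no early stopping).
    batch_norm : bool
        Append a batch-normalization layer after each hidden activation.
    random_state : int or None
        Seed for weight initialization and batch shuffling.
    """

    def __init__(self, hidden_sizes=(2000, 500, 2000), activation="tanh",
                 epochs=32, batch_size=16, learning_rate=1e-3,
                 batch_norm=True, random_state=None, dtype="float32",
                 verbose=0):
        self.hidden_sizes = hidden_sizes
        self.activation = activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.batch_norm = batch_norm
        self.random_state = random_state
        self.dtype = dtype
        self.verbose = verbose

    # ------------------------------------------------------------------

    def _validate_spec(self, n_features):
        if len(self.hidden_sizes) % 2 == 0 or len(self.hidden_sizes) == 0:
            raise OmiprogError(
                f"hidden_sizes must have an odd count; got {self.hidden_sizes}")
        if self.activation != "tanh":
            raise OmiprogError("only the tanh activation is supported")
        if self.epochs < 1:
            raise OmiprogError("epochs must be >= 1")
        sizes = list(self.hidden_sizes)
        if any(s > n_features for s in sizes):
            sizes = [min(s, n_features) for s in sizes]
            warnings.warn(
                f"hidden sizes {tuple(self.hidden_sizes)} shrunk to {tuple(sizes)} "
                f"for input width {n_features}")
        return sizes

    def _as_array(self, X, check_features):
        if isinstance(X, pd.DataFrame):
            if check_features and hasattr(self, "feature_names_"):
                if list(X.columns) != list(self.feature_names_):
                    missing = [c for c in self.feature_names_ if c not in set(X.columns)]
                    extra = [c for c in X.columns if c not in set(self.feature_names_)]
                    raise OmiprogError(
                        f"feature mismatch with training input; missing={missing[:5]} "
                        f"extra={extra[:5]} (showing up to 5)")
            arr = X.to_numpy(dtype=self.dtype)
        else:
            arr = np.asarray(X, dtype=self.dtype)
            if check_features and hasattr(self, "n_features_in_") \
                    and arr.shape[1] != self.n_features_in_:
                raise OmiprogError(
                    f"expected {self.n_features_in_} features, got {arr.shape[1]}")
        if not np.all(np.isfinite(arr)):
            raise OmiprogError("input contains non-finite values")
        return arr

    # ------------------------------------------------------------------

    def fit(self, X, y=None):
        arr = self._as_array(X, check_features=False)
        if arr.shape[0] < 2:
            raise OmiprogError("need at least 2 samples to train")
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
        self.n_features_in_ = arr.shape[1]
        sizes = self._validate_spec(arr.shape[1])
        self.hidden_sizes_ = tuple(sizes)
        self.bottleneck_size_ = sizes[len(sizes) // 2]

        rng = np.random.default_rng(self.random_state)
        dtype = np.dtype(self.dtype)
        widths = [arr.shape[1]] + sizes
        self._hidden = []
        for n_in, n_out in zip(widths[:-1], widths[1:]):
            block = {"dense": _Dense(rng, n_in, n_out, dtype)}
            if self.batch_norm:
                block["bn"] = _BatchNorm(n_out, dtype)
            self._hidden.append(block)
        self._out = _Dense(rng, sizes[-1], arr.shape[1], dtype)

        params = self._all_layers()
        adam_m = [[np.zeros_like(p) for p in layer.params()] for layer in params]
        adam_v = [[np.zeros_like(p) for p in layer.params()] for layer in params]
        # params_grads() is re-queried each step; m/v indexed in parallel
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = arr.shape[0]
        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                xb = arr[order[start:start + self.batch_size]]
                recon = self._forward(xb, training=True)
                diff = recon - xb
                losses.append(float(np.mean(diff * diff)))
                dout = (2.0 / diff.size) * diff
                self._backward(dout)
                step += 1
                lr_t = self.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
                for li, layer in enumerate(params):
                    for pi, (p, g) in enumerate(layer.params_grads()):
                        adam_m[li][pi] = b1 * adam_m[li][pi] + (1 - b1) * g
                        adam_v[li][pi] = b2 * adam_v[li][pi] + (1 - b2) * g * g
                        p -= lr_t * adam_m[li][pi] / (np.sqrt(adam_v[li][pi]) + eps)
            history.append(float(np.mean(losses)))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs} loss {history[-1]:.6f}")
        self.history_ = history
        return self

    def _all_layers(self):
        layers = []
        for block in self._hidden:
            layers.append(block["dense"])
            if "bn" in block:
                layers.append(block["bn"])
        layers.append(self._out)
        return layers

    def _forward(self, x, training, upto=None):
        h = x
        self._acts = []
        n_blocks = len(self._hidden) if upto is None else upto
        for block in self._hidden[:n_blocks]:
            z = block["dense"].forward(h)
            a = np.tanh(z)
            block["_a"] = a
            h = block["bn"].forward(a, training) if "bn" in block else a
        if upto is not None:
            return h
        return self._out.forward(h)

    def _backward(self, dout):
        dh = self._out.backward(dout)
        for block in reversed(self._hidden):
            if "bn" in block:
                dh = block["bn"].backward(dh)
            dh = dh * (1.0 - block["_a"] * block["_a"])  # tanh'
            dh = block["dense"].backward(dh)

    # ------------------------------------------------------------------

    def transform(self, X):
        """Deterministic forward pass to the bottleneck (inference mode)."""
        check_is_fitted(self, "history_")
        arr = self._as_array(X, check_features=True)
        mid = len(self._hidden) // 2 + 1
        out = self._forward(arr, training=False, upto=mid)
        if isinstance(X, pd.DataFrame):
            cols = [f"ae{j:03d}" for j in range(out.shape[1])]
            return pd.DataFrame(np.asarray(out, dtype=float), index=X.index, columns=cols)
        return np.asarray(out, dtype=float)

    encode = transform

    def reconstruct(self, X):
        """Full forward pass (inference mode)."""
        check_is_fitted(self, "history_")
        arr = self._as_array(X, check_features=True)
        return np.asarray(self._forward(arr, training=False), dtype=float)

    def bottleneck_activations(self, X, pre_batch_norm: bool = False):
        """Bottleneck activations, optionally before the batch-norm layer."""
        check_is_fitted(self, "history_")
        arr = self._as_array(X, check_features=True)
        mid = len(self._hidden) // 2 + 1
        if not pre_batch_norm:
            return np.asarray(self._forward(arr, training=False, upto=mid), dtype=float)
        self._forward(arr, training=False, upto=mid)
        return np.asarray(self._hidden[mid - 1]["_a"], dtype=float)
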