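"""Multilayer-perceptron classifier in plain NumPy.

Equal-width fully connected hidden layers, each linear -> batch
normalization (optional) -> ReLU -> dropout, with a softmax head trained
by categorical cross-entropy under the Adam optimizer.  Sized for tabular
feature inputs (tens of columns, thousands of rows), where mini-batch
matrix products in NumPy are entirely adequate.
"""

from __future__ import annotations

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


class MLPGestureClassifier:
    """ReLU MLP with optional batch normalization and dropout.

    Parameters
    ----------
    hidden_layers, hidden_units : architecture (equal-width layers).
    dropout : inverted-dropout rate applied after each hidden activation.
    batch_norm : insert a BN stage between each linear map and its ReLU.
    epochs, batch_size, learning_rate : Adam training recipe.
    seed : controls weight initialization, shuffling and dropout masks.
    """

    def __init__(
        self,
        hidden_layers: int = 3,
        hidden_units: int = 600,
        dropout: float = 0.2,
        batch_norm: bool = True,
        epochs: int = 2000,
        batch_size: int = 1024,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        if hidden_layers < 1 or hidden_units < 1:
            raise ValueError("need at least one hidden layer and one unit")
        if not 0 <= dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if epochs < 1 or batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        self.hidden_layers = hidden_layers
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.batch_norm = batch_norm
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    # -- forward pieces ----------------------------------------------------
    def _init_params(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        dims = [n_in] + [self.hidden_units] * self.hidden_layers + [n_out]
        self.W = [
            rng.standard_normal((dims[i], dims[i + 1])) * np.sqrt(2.0 / dims[i])
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        if self.batch_norm:
            h = self.hidden_units
            self.gamma = [np.ones(h) for _ in range(self.hidden_layers)]
            self.beta = [np.zeros(h) for _ in range(self.hidden_layers)]
            self.run_mean = [np.zeros(h) for _ in range(self.hidden_layers)]
            self.run_var = [np.ones(h) for _ in range(self.hidden_layers)]

    def _params(self) -> list[np.ndarray]:
        ps = list(self.W) + list(self.b)
        if self.batch_norm:
            ps += list(self.gamma) + list(self.beta)
        return ps

    def _forward_train(self, X: np.ndarray, rng: np.random.Generator):
        cache = []
        a = X
        for l in range(self.hidden_layers):
            z = a @ self.W[l] + self.b[l]
            if self.batch_norm:
                mu = z.mean(axis=0)
                varz = z.var(axis=0)
                inv = 1.0 / np.sqrt(varz + _BN_EPS)
                zhat = (z - mu) * inv
                u = self.gamma[l] * zhat + self.beta[l]
                self.run_mean[l] = _BN_MOMENTUM * self.run_mean[l] + (1 - _BN_MOMENTUM) * mu
                self.run_var[l] = _BN_MOMENTUM * self.run_var[l] + (1 - _BN_MOMENTUM) * varz
            else:
                zhat = inv = None
                u = z
            h = np.maximum(u, 0.0)
            if self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                out = h * mask
            else:
                mask = None
                out = h
            cache.append((a, z, zhat, inv, u, mask))
            a = out
        logits = a @ self.W[-1] + self.b[-1]
        return logits, a, cache

    def _forward_eval(self, X: np.ndarray) -> np.ndarray:
        a = X
        for l in range(self.hidden_layers):
            z = a @ self.W[l] + self.b[l]
            if self.batch_norm:
                z = (z - self.run_mean[l]) / np.sqrt(self.run_var[l] + _BN_EPS)
                z = self.gamma[l] * z + self.beta[l]
            a = np.maximum(z, 0.0)
        return a @ self.W[-1] + self.b[-1]

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPGestureClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, n_in = X.shape
        k = len(self.classes_)
        rng = np.random.default_rng(self.seed)
        self._init_params(n_in, k, rng)
        opt = _Adam(self._params(), self.learning_rate)
        onehot = np.eye(k)[y_idx]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                if len(idx) < 2 and self.batch_norm:
                    continue  # BN statistics are undefined on a single row
                self._step(X[idx], onehot[idx], opt, rng)
        return self

    def _step(self, Xb, Yb, opt, rng) -> None:
        B = len(Xb)
        logits, a_last, cache = self._forward_train(Xb, rng)
        probs = self._softmax(logits)
        dlogits = (probs - Yb) / B

        gW = [np.empty_like(w) for w in self.W]
        gb = [np.empty_like(b) for b in self.b]
        if self.batch_norm:
            ggam = [np.empty_like(g) for g in self.gamma]
            gbet = [np.empty_like(g) for g in self.beta]

        gW[-1] = a_last.T @ dlogits
        gb[-1] = dlogits.sum(axis=0)
        da = dlogits @ self.W[-1].T
        for l in range(self.hidden_layers - 1, -1, -1):
            a_prev, z, zhat, inv, u, mask = cache[l]
            if mask is not None:
                da = da * mask
            du = da * (u > 0)
            if self.batch_norm:
                ggam[l] = (du * zhat).sum(axis=0)
                gbet[l] = du.sum(axis=0)
                dzhat = du * self.gamma[l]
                # fused BN backward: dz = inv/B * (B*dzhat - sum(dzhat)
                #                                  - zhat * sum(dzhat*zhat))
                dz = (inv / B) * (
                    B * dzhat
                    - dzhat.sum(axis=0)
                    - zhat * (dzhat * zhat).sum(axis=0)
                )
            else:
                dz = du
            gW[l] = a_prev.T @ dz
            gb[l] = dz.sum(axis=0)
            da = dz @ self.W[l].T

        grads = gW + gb
        if self.batch_norm:
            grads += ggam + gbet
        opt.step(self._params(), grads)

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._softmax(self._forward_eval(np.asarray(X, dtype=float)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
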