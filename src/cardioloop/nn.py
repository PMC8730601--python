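"""Minimal NumPy neural networks for cardiovascular state decoding.

Implements exactly the architectures the pipeline needs, with full
backpropagation (including through time), inverted dropout, Adam with a
configurable first-moment decay, per-array L2-norm gradient clipping and L2
weight regularization:

* :class:`DenseLSTMClassifier` -- sequence input (13) -> dense(250) ->
  dropout(0.5) -> LSTM(100) -> dropout(0.25) -> softmax(4), per-step labels.
* :class:`DenseDenseClassifier` -- the no-memory control: the LSTM layer is
  replaced by a second dense layer of the same size.
* :class:`LSTMAutoencoder` -- LSTM encoder whose final hidden state (256) is
  the latent code, linear decoder back to the flattened window (2730).
* :class:`SparseAutoencoder` -- dense sigmoid bottleneck autoencoder
  (546 -> 50 -> 546) with L2 and a target-activation sparsity penalty.

Gradients are verified against central finite differences in the test
suite; all forward passes are deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DenseLSTMClassifier", "DenseDenseClassifier",
    "LSTMAutoencoder", "SparseAutoencoder", "softmax",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _glorot(rng, shape, dtype):
    lim = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


class _Adam:
    """Adam with per-array L2-norm gradient clipping and L2 penalty."""

    def __init__(self, params: dict, lr=0.01, beta1=0.8, beta2=0.999,
                 eps=1e-8, clip=2.0, l2=0.0005):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip, self.l2 = clip, l2
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict):
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            if self.l2 and not k.startswith("b"):
                g = g + self.l2 * p
            if self.clip:
                norm = float(np.sqrt(np.sum(g.astype(np.float64) ** 2)))
                if norm > self.clip:
                    g = g * (self.clip / norm)
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def _lstm_forward(A, Wx, Wh, b, h0=None, c0=None):
    """A: (B, T, D_in) -> hidden states (B, T, H) plus gate caches."""
    B, T, _ = A.shape
    H = Wh.shape[0]
    dtype = A.dtype
    h = np.zeros((B, H), dtype=dtype) if h0 is None else h0
    c = np.zeros((B, H), dtype=dtype) if c0 is None else c0
    Hs = np.empty((B, T, H), dtype=dtype)
    cache = {k: np.empty((B, T, H), dtype=dtype) for k in ("i", "f", "g", "o", "c", "tc")}
    cache["c_prev"] = np.empty((B, T, H), dtype=dtype)
    for t in range(T):
        z = A[:, t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H]); f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H]); o = _sigmoid(z[:, 3 * H:])
        cache["c_prev"][:, t] = c
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        Hs[:, t] = h
        for k, v in (("i", i), ("f", f), ("g", g), ("o", o), ("c", c), ("tc", tc)):
            cache[k][:, t] = v
    cache["Hs"] = Hs
    return Hs, h, c, cache


def _lstm_backward(dHs, A, Wx, Wh, cache, dh_last=None, dc_last=None, h0=None):
    """Backprop through time.  dHs: (B, T, H) upstream grad on every h_t.
    ``h0`` is the initial hidden state when it was nonzero in the forward."""
    B, T, H = cache["i"].shape
    dtype = A.dtype
    dWx = np.zeros_like(Wx); dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H, dtype=dtype)
    dA = np.empty_like(A)
    dh = np.zeros((B, H), dtype=dtype) if dh_last is None else dh_last.copy()
    dc = np.zeros((B, H), dtype=dtype) if dc_last is None else dc_last.copy()
    for t in range(T - 1, -1, -1):
        dh = dh + dHs[:, t]
        i, f, g, o = (cache[k][:, t] for k in ("i", "f", "g", "o"))
        tc = cache["tc"][:, t]
        c_prev = cache["c_prev"][:, t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di, dg, df = dc * g, dc * i, dc * c_prev
        dz = np.concatenate([
            di * i * (1 - i), df * f * (1 - f),
            dg * (1 - g * g), do * o * (1 - o)], axis=1)
        dWx += A[:, t].T @ dz
        if t > 0:
            h_prev = cache["Hs"][:, t - 1]
        else:
            h_prev = h0 if h0 is not None else np.zeros((B, H), dtype=dtype)
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dA[:, t] = dz @ Wx.T
        dh = dz @ Wh.T
        dc = dc * f
    return dA, dWx, dWh, db, dh, dc


class DenseLSTMClassifier:
    """Sequence classifier: dense(relu) -> dropout -> LSTM -> dropout -> softmax.

    ``fit`` follows the decoder training recipe: each epoch draws one batch
    of ``batch_fraction`` of the training sequences, takes a single Adam
    update, and stops early once the batch accuracy reaches
    ``early_stop_acc``.
    """

    def __init__(self, n_features=13, dense_units=250, lstm_units=100,
                 n_classes=4, dropout_dense=0.5, dropout_lstm=0.25,
                 lr=0.01, beta1=0.8, clip=2.0, l2=0.0005,
                 batch_fraction=0.75, early_stop_acc=0.98, max_epochs=500,
                 input_scale=1.0, seed=0, dtype=np.float32):
        self.cfg = dict(n_features=n_features, dense_units=dense_units,
                        lstm_units=lstm_units, n_classes=n_classes,
                        dropout_dense=dropout_dense, dropout_lstm=dropout_lstm,
                        lr=lr, beta1=beta1, clip=clip, l2=l2,
                        batch_fraction=batch_fraction,
                        early_stop_acc=early_stop_acc, max_epochs=max_epochs,
                        input_scale=input_scale, seed=seed)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        H, D, U, C = lstm_units, n_features, dense_units, n_classes
        self.params = {
            "Wd": _glorot(rng, (D, U), dtype), "bd": np.zeros(U, dtype=dtype),
            "Wx": _glorot(rng, (U, 4 * H), dtype), "Wh": _glorot(rng, (H, 4 * H), dtype),
            "bl": np.zeros(4 * H, dtype=dtype),
            "Wo": _glorot(rng, (H, C), dtype), "bo": np.zeros(C, dtype=dtype),
        }
        # forget-gate bias 1: standard LSTM initialization
        self.params["bl"][H:2 * H] = 1.0
        self._rng = rng
        self.history: list[dict] = []

    # -- forward ----------------------------------------------------------
    def _forward(self, X, train=False):
        p = self.params
        X = X.astype(self.dtype, copy=False) * self.dtype(self.cfg["input_scale"])
        A = np.maximum(X @ p["Wd"] + p["bd"], 0.0)
        cache = {"X": X, "A_pre_drop": A}
        if train and self.cfg["dropout_dense"] > 0:
            keep = 1.0 - self.cfg["dropout_dense"]
            mask = (self._rng.random(A.shape) < keep).astype(self.dtype) / keep
            A = A * mask
            cache["mask_d"] = mask
        Hs, h, c, lstm_cache = _lstm_forward(A, p["Wx"], p["Wh"], p["bl"])
        Hd = Hs
        if train and self.cfg["dropout_lstm"] > 0:
            keep = 1.0 - self.cfg["dropout_lstm"]
            mask = (self._rng.random(Hs.shape) < keep).astype(self.dtype) / keep
            Hd = Hs * mask
            cache["mask_l"] = mask
        logits = Hd @ p["Wo"] + p["bo"]
        cache.update(A=A, Hs=Hs, Hd=Hd, lstm=lstm_cache)
        return logits, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """X: (B, T, D) -> per-step class probabilities (B, T, C)."""
        logits, _ = self._forward(np.asarray(X), train=False)
        return softmax(logits.astype(np.float64))

    # -- backward ---------------------------------------------------------
    def _backward(self, cache, dlogits):
        p = self.params
        Hd = cache["Hd"]
        B, T, _ = Hd.shape
        dWo = Hd.reshape(B * T, -1).T @ dlogits.reshape(B * T, -1)
        dbo = dlogits.sum(axis=(0, 1))
        dHd = dlogits @ p["Wo"].T
        if "mask_l" in cache:
            dHd = dHd * cache["mask_l"]
        dA, dWx, dWh, dbl, _, _ = _lstm_backward(dHd, cache["A"], p["Wx"], p["Wh"], cache["lstm"])
        if "mask_d" in cache:
            dA = dA * cache["mask_d"]
        dA = dA * (cache["A_pre_drop"] > 0)
        X = cache["X"]
        dWd = X.reshape(-1, X.shape[-1]).T @ dA.reshape(-1, dA.shape[-1])
        dbd = dA.sum(axis=(0, 1))
        return {"Wd": dWd, "bd": dbd, "Wx": dWx, "Wh": dWh, "bl": dbl,
                "Wo": dWo, "bo": dbo}

    def loss_and_grads(self, X, y, train=True):
        """Mean per-step softmax cross-entropy; y: (B, T) int labels.
        Steps with label < 0 are masked out of the loss."""
        logits, cache = self._forward(np.asarray(X), train=train)
        P = softmax(logits.astype(np.float64))
        y = np.asarray(y)
        valid = y >= 0
        n = max(int(valid.sum()), 1)
        yc = np.where(valid, y, 0)
        logp = np.log(np.maximum(
            np.take_along_axis(P, yc[..., None], axis=-1)[..., 0], 1e-12))
        loss = -float(np.sum(logp[valid])) / n
        dlogits = P.copy()
        np.put_along_axis(dlogits, yc[..., None],
                          np.take_along_axis(dlogits, yc[..., None], axis=-1) - 1.0,
                          axis=-1)
        dlogits[~valid] = 0.0
        dlogits = (dlogits / n).astype(self.dtype)
        grads = self._backward(cache, dlogits)
        # overall accuracy = average accuracy across classes (balanced), the
        # quantity the early-stopping rule watches
        pred = np.argmax(P, axis=-1)[valid]
        truth = y[valid]
        accs = [np.mean(pred[truth == c] == c)
                for c in np.unique(truth)]
        acc = float(np.mean(accs))
        return loss, grads, acc

    # -- training ---------------------------------------------------------
    def fit(self, X, y, verbose=False):
        """X: (N, T, D) standardized sequences, y: (N, T) int step labels."""
        X = np.asarray(X); y = np.asarray(y)
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in training data")
        if np.unique(y[y >= 0]).size < 2:
            raise ValueError("training set has fewer than 2 classes")
        opt = _Adam(self.params, lr=self.cfg["lr"], beta1=self.cfg["beta1"],
                    clip=self.cfg["clip"], l2=self.cfg["l2"])
        n = X.shape[0]
        n_batch = max(1, int(round(self.cfg["batch_fraction"] * n)))
        for epoch in range(self.cfg["max_epochs"]):
            idx = self._rng.choice(n, size=n_batch, replace=False)
            loss, grads, acc = self.loss_and_grads(X[idx], y[idx], train=True)
            self.history.append({"epoch": epoch, "loss": loss, "acc": acc})
            if verbose and epoch % 10 == 0:
                print(f"epoch {epoch:4d} loss {loss:.4f} acc {acc:.3f}")
            if acc >= self.cfg["early_stop_acc"]:
                # stop with the weights that reached the criterion
                break
            opt.step(self.params, grads)
        return self

    # -- streaming --------------------------------------------------------
    def init_state(self):
        H = self.cfg["lstm_units"]
        return (np.zeros((1, H), dtype=self.dtype), np.zeros((1, H), dtype=self.dtype))

    def step(self, x, state):
        """One online step.  x: (D,) standardized vector; returns
        (probabilities (C,), new state)."""
        x = np.asarray(x, dtype=self.dtype).reshape(1, -1) * self.dtype(self.cfg["input_scale"])
        if x.shape[1] != self.cfg["n_features"]:
            raise ValueError(f"expected {self.cfg['n_features']} features, got {x.shape[1]}")
        p = self.params
        a = np.maximum(x @ p["Wd"] + p["bd"], 0.0)
        h, c = state
        H = self.cfg["lstm_units"]
        z = a @ p["Wx"] + h @ p["Wh"] + p["bl"]
        i = _sigmoid(z[:, :H]); f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H]); o = _sigmoid(z[:, 3 * H:])
        c = f * c + i * g
        h = o * np.tanh(c)
        probs = softmax((h @ p["Wo"] + p["bo"]).astype(np.float64))[0]
        return probs, (h, c)


class DenseDenseClassifier(DenseLSTMClassifier):
    """Memoryless control architecture: the LSTM layer is replaced by a
    second dense (relu) layer of the same size; everything else (dropout,
    optimizer, training recipe) is unchanged."""

    def __init__(self, **kwargs):
        super().__init__(**kwargs)
        rng = np.random.default_rng(self.cfg["seed"] + 1)
        H, U = self.cfg["lstm_units"], self.cfg["dense_units"]
        self.params.pop("Wx"); self.params.pop("Wh"); self.params.pop("bl")
        self.params["W2"] = _glorot(rng, (U, H), self.dtype)
        self.params["b2"] = np.zeros(H, dtype=self.dtype)

    def _forward(self, X, train=False):
        p = self.params
        X = X.astype(self.dtype, copy=False) * self.dtype(self.cfg["input_scale"])
        A = np.maximum(X @ p["Wd"] + p["bd"], 0.0)
        cache = {"X": X, "A_pre_drop": A}
        if train and self.cfg["dropout_dense"] > 0:
            keep = 1.0 - self.cfg["dropout_dense"]
            mask = (self._rng.random(A.shape) < keep).astype(self.dtype) / keep
            A = A * mask
            cache["mask_d"] = mask
        Hs = np.maximum(A @ p["W2"] + p["b2"], 0.0)
        cache["H_pre_drop"] = Hs
        Hd = Hs
        if train and self.cfg["dropout_lstm"] > 0:
            keep = 1.0 - self.cfg["dropout_lstm"]
            mask = (self._rng.random(Hs.shape) < keep).astype(self.dtype) / keep
            Hd = Hs * mask
            cache["mask_l"] = mask
        logits = Hd @ p["Wo"] + p["bo"]
        cache.update(A=A, Hs=Hs, Hd=Hd)
        return logits, cache

    def _backward(self, cache, dlogits):
        p = self.params
        Hd = cache["Hd"]
        B, T, _ = Hd.shape
        dWo = Hd.reshape(B * T, -1).T @ dlogits.reshape(B * T, -1)
        dbo = dlogits.sum(axis=(0, 1))
        dHd = dlogits @ p["Wo"].T
        if "mask_l" in cache:
            dHd = dHd * cache["mask_l"]
        dHd = dHd * (cache["H_pre_drop"] > 0)
        A = cache["A"]
        dW2 = A.reshape(-1, A.shape[-1]).T @ dHd.reshape(-1, dHd.shape[-1])
        db2 = dHd.sum(axis=(0, 1))
        dA = dHd @ p["W2"].T
        if "mask_d" in cache:
            dA = dA * cache["mask_d"]
        dA = dA * (cache["A_pre_drop"] > 0)
        X = cache["X"]
        dWd = X.reshape(-1, X.shape[-1]).T @ dA.reshape(-1, dA.shape[-1])
        dbd = dA.sum(axis=(0, 1))
        return {"Wd": dWd, "bd": dbd, "W2": dW2, "b2": db2, "Wo": dWo, "bo": dbo}

    def step(self, x, state):
        x = np.asarray(x, dtype=self.dtype).reshape(1, -1) * self.dtype(self.cfg["input_scale"])
        p = self.params
        a = np.maximum(x @ p["Wd"] + p["bd"], 0.0)
        h = np.maximum(a @ p["W2"] + p["b2"], 0.0)
        probs = softmax((h @ p["Wo"] + p["bo"]).astype(np.float64))[0]
        return probs, state


class LSTMAutoencoder:
    """LSTM autoencoder: recurrent encoder, dense reconstruction layer.

    The encoder LSTM consumes the window as a (T, D) sequence; its final
    hidden state (``hidden_units``) is the latent code, reconstructed back
    to the flattened window (T*D output units) by a dense linear decoder.
    Loss is mean squared reconstruction error.
    """

    def __init__(self, n_steps=210, n_features=13, hidden_units=256,
                 lr=0.003, beta1=0.9, clip=2.0, l2=0.0,
                 batch_size=256, epochs=4, input_scale=1.0, seed=0,
                 dtype=np.float32):
        self.cfg = dict(n_steps=n_steps, n_features=n_features,
                        hidden_units=hidden_units, lr=lr, beta1=beta1,
                        clip=clip, l2=l2, batch_size=batch_size,
                        epochs=epochs, input_scale=input_scale, seed=seed)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        D, H = n_features, hidden_units
        out = n_steps * n_features
        self.params = {
            "Wx": _glorot(rng, (D, 4 * H), dtype), "Wh": _glorot(rng, (H, 4 * H), dtype),
            "bl": np.zeros(4 * H, dtype=dtype),
            "Wd": _glorot(rng, (H, out), dtype), "bd": np.zeros(out, dtype=dtype),
        }
        self.params["bl"][H:2 * H] = 1.0
        self._rng = rng
        self.train_losses_: np.ndarray | None = None

    @property
    def input_size(self) -> int:
        return self.cfg["n_steps"] * self.cfg["n_features"]

    def _check(self, X):
        X = np.asarray(X)
        if X.ndim == 2:
            if X.shape[1] != self.input_size:
                raise ValueError(
                    f"window width {X.shape[1]} != encoder input {self.input_size}")
            X = X.reshape(-1, self.cfg["n_steps"], self.cfg["n_features"])
        return X.astype(self.dtype, copy=False)

    def _encode_batched(self, X, batch=256):
        """Final hidden state per window, bounded-memory inference."""
        p = self.params
        g = self.dtype(self.cfg["input_scale"])
        out = np.empty((X.shape[0], self.cfg["hidden_units"]))
        for s in range(0, X.shape[0], batch):
            _, h, _, _ = _lstm_forward(X[s:s + batch] * g, p["Wx"], p["Wh"], p["bl"])
            out[s:s + batch] = h
        return out

    def hidden(self, X) -> np.ndarray:
        """Latent codes (B, hidden_units) for the given windows."""
        return self._encode_batched(self._check(X))

    def reconstruct(self, X) -> np.ndarray:
        X = self._check(X)
        h = self._encode_batched(X)
        return h @ self.params["Wd"].astype(np.float64) + self.params["bd"]

    def loss(self, X) -> np.ndarray:
        """Per-window mean squared reconstruction error."""
        X = self._check(X)
        out = np.empty(X.shape[0])
        p = self.params
        for s in range(0, X.shape[0], 256):
            xb = X[s:s + 256]
            h = self._encode_batched(xb)
            xhat = h @ p["Wd"].astype(np.float64) + p["bd"]
            flat = xb.reshape(xb.shape[0], -1).astype(np.float64)
            out[s:s + 256] = np.mean((xhat - flat) ** 2, axis=1)
        return out

    def _step(self, X, opt):
        p = self.params
        B = X.shape[0]
        Xs = X * self.dtype(self.cfg["input_scale"])
        Hs, h, c, cache = _lstm_forward(Xs, p["Wx"], p["Wh"], p["bl"])
        flat = X.reshape(B, -1)
        xhat = h @ p["Wd"] + p["bd"]
        err = (xhat - flat).astype(self.dtype)
        loss = float(np.mean(err.astype(np.float64) ** 2))
        dxhat = (2.0 / err.size) * err
        dWd = h.T @ dxhat
        dbd = dxhat.sum(axis=0)
        dh_last = dxhat @ p["Wd"].T
        dHs = np.zeros_like(Hs)
        _, dWx, dWh, dbl, _, _ = _lstm_backward(dHs, Xs, p["Wx"], p["Wh"], cache,
                                                dh_last=dh_last)
        opt.step(p, {"Wx": dWx, "Wh": dWh, "bl": dbl, "Wd": dWd, "bd": dbd})
        return loss

    def fit(self, X, refine_decoder: bool = True):
        """Train the encoder by backpropagation, then (optionally) set the
        dense decoder to its exact ridge least-squares optimum given the
        final encoder codes -- the decoder is linear, so its best weights
        for the training windows have a closed form.  This converges the
        reconstruction of the known manifold far beyond what the gradient
        steps alone reach in the same time."""
        X = self._check(X)
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in training windows")
        opt = _Adam(self.params, lr=self.cfg["lr"], beta1=self.cfg["beta1"],
                    clip=self.cfg["clip"], l2=self.cfg["l2"])
        n = X.shape[0]
        bs = min(self.cfg["batch_size"], n)
        for _ in range(self.cfg["epochs"]):
            order = self._rng.permutation(n)
            for s in range(0, n, bs):
                self._step(X[order[s:s + bs]], opt)
        if refine_decoder:
            H = self._encode_batched(X)                      # (n, H)
            flat = X.reshape(n, -1).astype(np.float64)
            Hc = np.column_stack([H, np.ones(n)])
            lam = max(self.cfg["l2"], 1e-6)
            G = Hc.T @ Hc + lam * np.eye(Hc.shape[1])
            W = np.linalg.solve(G, Hc.T @ flat)
            self.params["Wd"] = W[:-1].astype(self.dtype)
            self.params["bd"] = W[-1].astype(self.dtype)
        self.train_losses_ = self.loss(X)
        return self


class SparseAutoencoder:
    """Dense bottleneck autoencoder with sigmoid code units.

    Loss = MSE + l2 * ||W||^2 / 2 + sparsity_weight * KL(target || mean
    activation).  With the target activation at 1.0 the KL term only pushes
    code units toward saturation and the model behaves as a plain
    regularized autoencoder.
    """

    def __init__(self, n_inputs=546, hidden_units=50, l2=0.1,
                 sparsity_target=1.0, sparsity_weight=0.01,
                 lr=0.003, batch_size=256, epochs=30, seed=0, dtype=np.float32):
        self.cfg = dict(n_inputs=n_inputs, hidden_units=hidden_units, l2=l2,
                        sparsity_target=sparsity_target,
                        sparsity_weight=sparsity_weight, lr=lr,
                        batch_size=batch_size, epochs=epochs, seed=seed)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.params = {
            "W1": _glorot(rng, (n_inputs, hidden_units), dtype),
            "b1": np.zeros(hidden_units, dtype=dtype),
            "W2": _glorot(rng, (hidden_units, n_inputs), dtype),
            "b2": np.zeros(n_inputs, dtype=dtype),
        }
        self._rng = rng
        self.train_losses_: np.ndarray | None = None

    @property
    def input_size(self) -> int:
        return self.cfg["n_inputs"]

    def _check(self, X):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.cfg["n_inputs"]:
            raise ValueError(f"expected (n, {self.cfg['n_inputs']}) windows")
        return X.astype(self.dtype, copy=False)

    def hidden(self, X) -> np.ndarray:
        X = self._check(X)
        return _sigmoid(X @ self.params["W1"] + self.params["b1"]).astype(np.float64)

    def reconstruct(self, X) -> np.ndarray:
        h = self.hidden(X)
        return h @ self.params["W2"].astype(np.float64) + self.params["b2"]

    def loss(self, X) -> np.ndarray:
        X = self._check(X)
        xhat = self.reconstruct(X)
        return np.mean((xhat - X.astype(np.float64)) ** 2, axis=1)

    def fit(self, X):
        X = self._check(X)
        p = self.params
        opt = _Adam(p, lr=self.cfg["lr"], beta1=0.9, clip=2.0, l2=self.cfg["l2"])
        n = X.shape[0]
        bs = min(self.cfg["batch_size"], n)
        rho = self.cfg["sparsity_target"]
        beta = self.cfg["sparsity_weight"]
        for _ in range(self.cfg["epochs"]):
            order = self._rng.permutation(n)
            for s in range(0, n, bs):
                xb = X[order[s:s + bs]]
                B = xb.shape[0]
                h = _sigmoid(xb @ p["W1"] + p["b1"])
                xhat = h @ p["W2"] + p["b2"]
                err = xhat - xb
                dxhat = (2.0 / err.size) * err
                dW2 = h.T @ dxhat
                db2 = dxhat.sum(axis=0)
                dh = dxhat @ p["W2"].T
                if beta > 0:
                    rho_hat = np.clip(h.mean(axis=0), 1e-6, 1 - 1e-6)
                    drho = (-rho / rho_hat + (1 - rho) / (1 - rho_hat)) / h.shape[1]
                    dh = dh + (beta / B) * drho
                dz1 = dh * h * (1 - h)
                dW1 = xb.T @ dz1
                db1 = dz1.sum(axis=0)
                opt.step(p, {"W1": dW1.astype(self.dtype), "b1": db1.astype(self.dtype),
                             "W2": dW2.astype(self.dtype), "b2": db2.astype(self.dtype)})
        self.train_losses_ = self.loss(X)
        return self
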