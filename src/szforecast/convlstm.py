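"""A compact ConvLSTM sequence classifier implemented in numpy.

The reference preictal/interictal classifier: per-time-step 1-D convolution
blocks over the QEEG feature vector, a single LSTM layer over the epoch
sequence, dropout, and a sigmoid head, trained with class-weighted binary
cross-entropy and Adam, early-stopped on validation loss.

Convolutions use a channels-last shift-matmul realization (one GEMM per
kernel tap) so everything runs through BLAS.  All gradients are derived by
hand and verified against central finite differences in the test suite.
Training is deterministic given the seed (single-threaded numpy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


@dataclass
class NetConfig:
    n_features: int = 1
    seq_len: int = 15
    conv_channels: tuple[int, ...] = (16, 32)
    kernel: int = 3
    conv_stride: int = 2
    hidden: int = 32
    dropout: float = 0.2
    dtype: type = np.float32


class ConvLSTMNet:
    """Conv blocks over features, LSTM over time, sigmoid head.

    Conv weights are stored as (k, cin, cout) for the shift-matmul
    realization; activations are channels-last (N, L, C).
    """

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        self.cfg = cfg
        dt = cfg.dtype
        p: dict[str, np.ndarray] = {}
        cin = 1
        for li, cout in enumerate(cfg.conv_channels):
            scale = np.sqrt(2.0 / (cin * cfg.kernel))
            p[f"W{li}"] = rng.normal(0, scale, size=(cfg.kernel, cin, cout)).astype(dt)
            p[f"b{li}"] = np.zeros(cout, dtype=dt)
            cin = cout
        self.lstm_in = cfg.conv_channels[-1] if cfg.conv_channels else cfg.n_features
        H = cfg.hidden
        sx = np.sqrt(1.0 / self.lstm_in)
        sh = np.sqrt(1.0 / H)
        p["Wx"] = rng.normal(0, sx, size=(self.lstm_in, 4 * H)).astype(dt)
        p["Wh"] = rng.normal(0, sh, size=(H, 4 * H)).astype(dt)
        p["bl"] = np.zeros(4 * H, dtype=dt)
        p["bl"][H : 2 * H] = 1.0  # forget-gate bias
        p["wout"] = rng.normal(0, sh, size=H).astype(dt)
        p["bout"] = np.zeros(1, dtype=dt)
        self.params = p

    # ---------------------------------------------------------- conv stack
    def _conv_forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        """X (B, T, F) -> (B, T, C_last) after conv stack + global pooling."""
        cfg = self.cfg
        if not cfg.conv_channels:  # degenerate pure-LSTM variant
            return X, []
        B, T, F = X.shape
        pad = cfg.kernel // 2
        s = max(1, cfg.conv_stride)
        cur = X.reshape(B * T, F, 1)
        caches = []
        for li in range(len(cfg.conv_channels)):
            W = self.params[f"W{li}"]
            n, ln, cin = cur.shape
            lout = (ln + s - 1) // s
            Xp = np.zeros((n, ln + 2 * pad, cin), dtype=cur.dtype)
            Xp[:, pad : pad + ln, :] = cur
            z = np.empty((n, lout, W.shape[2]), dtype=cur.dtype)
            z[:] = self.params[f"b{li}"]
            flatz = z.reshape(n * lout, -1)
            for j in range(cfg.kernel):
                seg = Xp[:, j : j + (lout - 1) * s + 1 : s, :]
                flatz += seg.reshape(n * lout, cin) @ W[j]
            a = np.maximum(z, 0.0)
            caches.append((Xp, z, ln))
            cur = a
        pooled = cur.mean(axis=1)  # global average pool -> (N, C)
        caches.append(cur.shape)
        return pooled.reshape(B, T, -1), caches

    def _conv_backward(self, dseq: np.ndarray, caches: list) -> None:
        cfg = self.cfg
        if not cfg.conv_channels:
            return
        B, T, C = dseq.shape
        pad = cfg.kernel // 2
        s = max(1, cfg.conv_stride)
        last_shape = caches[-1]
        dcur = np.broadcast_to(
            dseq.reshape(B * T, 1, C) / last_shape[1], last_shape
        ).astype(dseq.dtype)
        for li in reversed(range(len(cfg.conv_channels))):
            Xp, z, ln = caches[li]
            n, lnp, cin = Xp.shape
            lout = z.shape[1]
            dz = np.where(z > 0, dcur, 0)
            W = self.params[f"W{li}"]
            cout = W.shape[2]
            flat_dz = dz.reshape(n * lout, cout)
            self.grads[f"b{li}"] += dz.sum(axis=(0, 1))
            dXp = np.zeros_like(Xp)
            for j in range(cfg.kernel):
                sl = slice(j, j + (lout - 1) * s + 1, s)
                seg = Xp[:, sl, :].reshape(n * lout, cin)
                self.grads[f"W{li}"][j] += seg.T @ flat_dz
                dXp[:, sl, :] += (flat_dz @ W[j].T).reshape(n, lout, cin)
            dcur = dXp[:, pad : pad + ln, :]
        # dcur now holds dX (unused upstream)

    # ---------------------------------------------------------- LSTM
    def _lstm_forward(self, S: np.ndarray) -> tuple[np.ndarray, dict]:
        B, T, _ = S.shape
        H = self.cfg.hidden
        p = self.params
        h = np.zeros((B, H), dtype=S.dtype)
        c = np.zeros((B, H), dtype=S.dtype)
        xproj = S.reshape(B * T, -1) @ p["Wx"] + p["bl"]
        xproj = xproj.reshape(B, T, 4 * H)
        cache = {"i": [], "f": [], "g": [], "o": [], "c": [], "h": [], "tanhc": []}
        for t in range(T):
            a = xproj[:, t, :] + h @ p["Wh"]
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            for k, v in zip(("i", "f", "g", "o", "c", "h", "tanhc"), (i, f, g, o, c, h, tc)):
                cache[k].append(v)
        return h, cache

    def _lstm_backward(self, dh_last: np.ndarray, S: np.ndarray, cache: dict) -> np.ndarray:
        B, T, _ = S.shape
        H = self.cfg.hidden
        p = self.params
        da_all = np.empty((B, T, 4 * H), dtype=S.dtype)
        dh = dh_last
        dc = np.zeros((B, H), dtype=S.dtype)
        zero = np.zeros((B, H), dtype=S.dtype)
        for t in reversed(range(T)):
            i, f, g, o = (cache[k][t] for k in ("i", "f", "g", "o"))
            tc = cache["tanhc"][t]
            c_prev = cache["c"][t - 1] if t > 0 else zero
            h_prev = cache["h"][t - 1] if t > 0 else zero
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            da_all[:, t, :] = da
            self.grads["Wh"] += h_prev.T @ da
            dh = da @ p["Wh"].T
            dc = dc * f
        flat_da = da_all.reshape(B * T, 4 * H)
        self.grads["Wx"] += S.reshape(B * T, -1).T @ flat_da
        self.grads["bl"] += flat_da.sum(axis=0)
        return (flat_da @ p["Wx"].T).reshape(B, T, -1)

    # ---------------------------------------------------------- full net
    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        dropout_mask: np.ndarray | None = None,
    ) -> tuple[np.ndarray, dict]:
        X = np.asarray(X, dtype=self.cfg.dtype)
        seq, conv_cache = self._conv_forward(X)
        h, lstm_cache = self._lstm_forward(seq)
        if train and dropout_mask is not None:
            h_drop = h * dropout_mask
        else:
            h_drop = h
        logits = h_drop @ self.params["wout"] + self.params["bout"][0]
        cache = {
            "seq": seq,
            "conv": conv_cache,
            "lstm": lstm_cache,
            "h_drop": h_drop,
            "mask": dropout_mask if train else None,
        }
        return logits, cache

    def loss_and_grad(
        self,
        X: np.ndarray,
        y: np.ndarray,
        sample_weight: np.ndarray,
        dropout_mask: np.ndarray | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Weighted BCE loss and parameter gradients for one batch."""
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        logits, cache = self.forward(X, train=True, dropout_mask=dropout_mask)
        B = X.shape[0]
        w = np.asarray(sample_weight, dtype=self.cfg.dtype)
        y = np.asarray(y, dtype=self.cfg.dtype)
        loss = float(np.mean(w * (_softplus(logits) - y * logits)))
        dlogit = (w * (_sigmoid(logits) - y) / B).astype(self.cfg.dtype)
        self.grads["wout"] += cache["h_drop"].T @ dlogit
        self.grads["bout"] += dlogit.sum(keepdims=True)
        dh = np.outer(dlogit, self.params["wout"])
        if cache["mask"] is not None:
            dh = dh * cache["mask"]
        dseq = self._lstm_backward(dh, cache["seq"], cache["lstm"])
        self._conv_backward(dseq, cache["conv"])
        return loss, self.grads

    def predict_logits(self, X: np.ndarray, batch: int = 1024) -> np.ndarray:
        out = np.empty(X.shape[0])
        for lo in range(0, X.shape[0], batch):
            sl = slice(lo, min(lo + batch, X.shape[0]))
            out[sl] = self.forward(X[sl])[0]
        return out

    def predict_proba(self, X: np.ndarray, batch: int = 1024) -> np.ndarray:
        p = _sigmoid(self.predict_logits(X, batch))
        return np.clip(p, 0.0, 1.0)

    def eval_loss(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray) -> float:
        logits = self.predict_logits(X)
        return float(np.mean(sample_weight * (_softplus(logits) - y * logits)))


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(params[k].dtype)


def class_weights(y: np.ndarray) -> np.ndarray:
    """Inverse-prevalence sample weights (mean weight 1)."""
    n = len(y)
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training labels contain a single class")
    return np.where(y > 0.5, n / (2.0 * n_pos), n / (2.0 * n_neg))


@dataclass
class FitResult:
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int


def fit_network(
    net: ConvLSTMNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    lr: float = 3e-3,
    batch_size: int = 128,
    max_epochs: int = 20,
    patience: int = 4,
    seed: int = 0,
) -> FitResult:
    """Mini-batch Adam with class weighting and validation early stopping.

    Keeps the parameters from the best validation epoch.  Non-finite loss
    aborts with diagnostics.
    """
    rng = np.random.default_rng(seed)
    dt = net.cfg.dtype
    X_train = np.asarray(X_train, dtype=dt)
    X_val = np.asarray(X_val, dtype=dt)
    w_train = class_weights(y_train)
    w_val = (
        class_weights(y_val)
        if 0 < y_val.sum() < len(y_val)
        else np.ones(len(y_val))
    )
    opt = Adam(net.params, lr=lr)
    n = X_train.shape[0]
    best_val = np.inf
    best_params = {k: v.copy() for k, v in net.params.items()}
    best_epoch = -1
    bad = 0
    train_losses, val_losses = [], []
    p_drop = net.cfg.dropout
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            mask = None
            if p_drop > 0:
                mask = (
                    (rng.random((len(idx), net.cfg.hidden)) >= p_drop) / (1 - p_drop)
                ).astype(dt)
            loss, grads = net.loss_and_grad(
                X_train[idx], y_train[idx], w_train[idx], dropout_mask=mask
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {lo // batch_size}"
                )
            opt.step(net.params, grads)
            ep_loss += loss * len(idx)
        train_losses.append(ep_loss / n)
        val_loss = net.eval_loss(X_val, y_val, w_val)
        val_losses.append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in net.params.items()}
            best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if bad > patience:
                break
    net.params = best_params
    return FitResult(train_losses, val_losses, best_epoch)
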