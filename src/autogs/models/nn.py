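"""Minimal CPU neural-network engine: layers with explicit forward/backward
passes, Adam, and a training loop with validation-based early stopping.

Shapes follow the channels-first convention: 1-D inputs are (N, C, L) and
2-D inputs (N, C, H, W).  All randomness (weight init, batch order,
dropout) flows from a single ``numpy.random.Generator``, so a fixed seed
gives bit-identical training runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g):
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T


class Conv1d(Layer):
    """1-D convolution on (N, C, L); padding 'valid' or 'same'."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 padding: str = "valid"):
        scale = np.sqrt(2.0 / (c_in * k))
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in, k)))
        self.b = Param(np.zeros(c_out))
        self.k = k
        self.padding = padding
        self._cols = None
        self._in_shape = None

    def params(self):
        return [self.w, self.b]

    def _pads(self):
        if self.padding == "same":
            total = self.k - 1
            return total // 2, total - total // 2
        return 0, 0

    def forward(self, x, train):
        pl, pr = self._pads()
        if pl or pr:
            x = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._in_shape = x.shape
        n, c, lp = x.shape
        win = sliding_window_view(x, self.k, axis=2)  # (n, c, L_out, k)
        cols = win.transpose(0, 2, 1, 3).reshape(n, lp - self.k + 1, c * self.k)
        self._cols = cols
        f = self.w.value.shape[0]
        y = cols @ self.w.value.reshape(f, -1).T + self.b.value
        return y.transpose(0, 2, 1)  # (n, f, L_out)

    def backward(self, g):
        n, f, l_out = g.shape
        gt = g.transpose(0, 2, 1)  # (n, L_out, f)
        wmat = self.w.value.reshape(f, -1)
        self.w.grad += np.einsum("nlf,nlc->fc", gt, self._cols).reshape(self.w.value.shape)
        self.b.grad += gt.sum(axis=(0, 1))
        dcols = (gt @ wmat).reshape(n, l_out, -1, self.k)  # (n, L_out, c, k)
        dx = np.zeros(self._in_shape)
        for kk in range(self.k):
            dx[:, :, kk : kk + l_out] += dcols[:, :, :, kk].transpose(0, 2, 1)
        pl, pr = self._pads()
        if pl or pr:
            dx = dx[:, :, pl : dx.shape[2] - pr or None]
        return dx


class Conv2d(Layer):
    """k x k convolution on (N, C, H, W) with symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 pad: int = 1):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out))
        self.k = k
        self.pad = pad
        self._cols = None
        self._in_shape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        p = self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._in_shape = x.shape
        n, c, hp, wp = x.shape
        k = self.k
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (n,c,Ho,Wo,k,k)
        ho, wo = hp - k + 1, wp - k + 1
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        self._cols = cols
        self._out_hw = (ho, wo)
        f = self.w.value.shape[0]
        y = cols @ self.w.value.reshape(f, -1).T + self.b.value  # (n, HoWo, f)
        return y.transpose(0, 2, 1).reshape(n, f, ho, wo)

    def backward(self, g):
        n, f, ho, wo = g.shape
        k = self.k
        gt = g.reshape(n, f, ho * wo).transpose(0, 2, 1)  # (n, HoWo, f)
        self.w.grad += np.einsum("nlf,nlc->fc", gt, self._cols).reshape(self.w.value.shape)
        self.b.grad += gt.sum(axis=(0, 1))
        wmat = self.w.value.reshape(f, -1)
        dcols = (gt @ wmat).reshape(n, ho, wo, -1, k, k)  # (n,Ho,Wo,c,k,k)
        dx = np.zeros(self._in_shape)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + ho, j : j + wo] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        p = self.pad
        if p:
            dx = dx[:, :, p:-p, p:-p]
        return dx


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, size: int):
        self.size = size
        self._idx = None
        self._in_shape = None

    def forward(self, x, train):
        s = self.size
        self._in_shape = x.shape
        n, c, l = x.shape
        lq = l // s
        xr = x[:, :, : lq * s].reshape(n, c, lq, s)
        self._idx = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._idx[..., None], axis=3)[..., 0]

    def backward(self, g):
        n, c, l = self._in_shape
        s = self.size
        lq = l // s
        dxr = np.zeros((n, c, lq, s))
        np.put_along_axis(dxr, self._idx[..., None], g[..., None], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, :, : lq * s] = dxr.reshape(n, c, lq * s)
        return dx


class MaxPool2d(Layer):
    """2x2 max pooling with ceil semantics (odd edges padded with -inf)."""

    def __init__(self):
        self._idx = None
        self._in_shape = None
        self._pad_hw = None

    def forward(self, x, train):
        self._in_shape = x.shape
        n, c, h, w = x.shape
        ph, pw = h % 2, w % 2
        self._pad_hw = (ph, pw)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
        h2, w2 = x.shape[2], x.shape[3]
        xw = (
            x.reshape(n, c, h2 // 2, 2, w2 // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 // 2, w2 // 2, 4)
        )
        self._idx = xw.argmax(axis=4)
        return np.take_along_axis(xw, self._idx[..., None], axis=4)[..., 0]

    def backward(self, g):
        n, c, h, w = self._in_shape
        ph, pw = self._pad_hw
        h2, w2 = h + ph, w + pw
        dxw = np.zeros((n, c, h2 // 2, w2 // 2, 4))
        np.put_along_axis(dxw, self._idx[..., None], g[..., None], axis=4)
        dx = (
            dxw.reshape(n, c, h2 // 2, w2 // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2, w2)
        )
        return dx[:, :, :h, :w]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x, train):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainConfig:
    """Gradient-descent settings shared by the convolutional models."""

    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    lr: float = 1e-3

    def __post_init__(self):
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class FitHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    epochs_run: int = 0


def _index(x, idx):
    if isinstance(x, tuple):
        return tuple(a[idx] for a in x)
    return x[idx]


def _n_rows(x):
    return x[0].shape[0] if isinstance(x, tuple) else x.shape[0]


class NumpyNet:
    """Base class for the convolutional regressors.

    Subclasses build ``self.net`` (or override forward/backward for
    multi-branch topologies) and define ``_prep(x)`` mapping the encoded
    tensor to network input.  Targets are standardized internally during
    fit and de-standardized at predict time.
    """

    def __init__(self, seed: int = 0, lr: float | None = None):
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.y_mean = 0.0
        self.y_std = 1.0
        self.history = FitHistory()
        self._built = False
        self.lr_override = lr

    # -- subclass API -------------------------------------------------
    def build(self, input_shape: tuple[int, ...]) -> None:  # pragma: no cover
        raise NotImplementedError

    def _prep(self, x):
        return x

    def net_forward(self, x, train: bool) -> np.ndarray:
        return self.net.forward(x, train)

    def net_backward(self, g: np.ndarray) -> None:
        self.net.backward(g)

    def parameters(self) -> list[Param]:
        return self.net.params()

    def _extra_state(self) -> dict:
        return {}

    def _set_extra_state(self, extra: dict) -> None:
        pass

    def get_state(self) -> dict:
        """Everything needed to restore eval-mode behaviour after rebuild."""
        return {
            "weights": self.get_weights(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "extra": self._extra_state(),
        }

    def set_state(self, state: dict, input_shape: tuple[int, ...]) -> None:
        self._set_extra_state(state.get("extra", {}))
        if not self._built:
            self.build(tuple(input_shape))
            self._built = True
        self.set_weights(state["weights"])
        self.y_mean = float(state["y_mean"])
        self.y_std = float(state["y_std"])

    # -- weights ------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.value.shape} vs {w.shape}")
            p.value[...] = w

    # -- training -----------------------------------------------------
    def fit(self, x_train, y_train, x_val=None, y_val=None,
            config: TrainConfig | None = None) -> "NumpyNet":
        cfg = config or TrainConfig()
        if self.lr_override is not None:
            cfg = TrainConfig(cfg.batch_size, cfg.max_epochs, cfg.patience, self.lr_override)
        x_train = self._prep(x_train)
        y_train = np.asarray(y_train, dtype=np.float64).ravel()
        n = _n_rows(x_train)
        if not self._built:
            if isinstance(x_train, tuple):
                shape = tuple(tuple(a.shape[1:]) for a in x_train)
            else:
                shape = tuple(x_train.shape[1:])
            self.build(shape)
            self._built = True
        self.y_mean = float(y_train.mean())
        self.y_std = float(y_train.std()) or 1.0
        yt = (y_train - self.y_mean) / self.y_std
        have_val = x_val is not None and _n_rows(self._prep(x_val)) > 0
        if have_val:
            x_val = self._prep(x_val)
            yv = (np.asarray(y_val, dtype=np.float64).ravel() - self.y_mean) / self.y_std

        batch = min(cfg.batch_size, n)
        opt = Adam(self.parameters(), lr=cfg.lr)
        best_val = np.inf
        best_weights = self.get_weights()
        bad_epochs = 0
        hist = FitHistory()
        for epoch in range(cfg.max_epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                xb = _index(x_train, idx)
                yb = yt[idx]
                opt.zero_grad()
                pred = self.net_forward(xb, train=True).ravel()
                err = pred - yb
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "reduce the learning rate or check the inputs"
                    )
                self.net_backward((2.0 * err / len(idx)).reshape(-1, 1))
                opt.step()
                losses.append(loss)
            hist.train_loss.append(float(np.mean(losses)))
            hist.epochs_run = epoch + 1
            if have_val:
                pv = self._eval_forward(x_val).ravel()
                vloss = float(np.mean((pv - yv) ** 2))
                hist.val_loss.append(vloss)
                if vloss < best_val - 1e-12:
                    best_val = vloss
                    best_weights = self.get_weights()
                    hist.best_epoch = epoch
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs >= cfg.patience:
                        break
            else:
                best_weights = self.get_weights()
                hist.best_epoch = epoch
        self.set_weights(best_weights)
        self.history = hist
        return self

    def _eval_forward(self, x_prepped, chunk: int = 512) -> np.ndarray:
        outs = []
        n = _n_rows(x_prepped)
        for start in range(0, n, chunk):
            xb = _index(x_prepped, slice(start, start + chunk))
            outs.append(self.net_forward(xb, train=False))
        return np.concatenate(outs, axis=0)

    def predict(self, x) -> np.ndarray:
        if not self._built:
            raise RuntimeError("model is not fitted")
        z = self._eval_forward(self._prep(x)).ravel()
        return z * self.y_std + self.y_mean
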