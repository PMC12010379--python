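"""Convolutional genomic-prediction architectures.

Four networks, each tied to one genotype encoding:

- :class:`DeepGSNet` — dosage vector: one conv layer, max pooling, a fully
  connected layer with ReLU, dropout 0.05, scalar head.
- :class:`DLGWASNet` — (4, L) one-hot: two parallel conv branches at
  different kernel scales merged by elementwise addition, then fully
  connected layers.
- :class:`DNNGPNet` — 150-dim PCA scores: exactly three conv layers, fully
  connected layers, one dropout layer.
- :class:`SoyDNGPNet` — (3, S, S) one-hot image: VGG-style 3x3 conv blocks
  with channel doubling and 2x2 downsampling, small dense head.

Kernel sizes and widths are tunable defaults; the structural contracts
(layer counts, merge semantics, encodings) are fixed.
"""

from __future__ import annotations

import numpy as np

from autogs.models.nn import (
    Conv1d,
    Conv2d,
    Dense,
    Dropout,
    Flatten,
    MaxPool1d,
    MaxPool2d,
    NumpyNet,
    ReLU,
    Sequential,
)


class DeepGSNet(NumpyNet):
    """Single-branch 1-D CNN over the dosage vector."""

    def __init__(self, seed: int = 0, n_filters: int = 8, kernel: int = 18,
                 pool: int = 2, hidden: int = 32, dropout: float = 0.05,
                 lr: float | None = None):
        super().__init__(seed=seed, lr=lr)
        self.n_filters = n_filters
        self.kernel = kernel
        self.pool = pool
        self.hidden = hidden
        self.dropout = dropout

    def _prep(self, x):
        x = np.asarray(x, dtype=np.float64)
        return (x - 1.0)[:, None, :]  # (n, 1, L), centered dosage

    def build(self, input_shape):
        _, L = input_shape
        if L < self.kernel:
            raise ValueError(f"input length {L} < kernel size {self.kernel}")
        l_conv = L - self.kernel + 1
        l_pool = l_conv // self.pool
        if l_pool < 1:
            raise ValueError(f"input length {L} too short for pool size {self.pool}")
        self.net = Sequential([
            Conv1d(1, self.n_filters, self.kernel, self.rng),
            ReLU(),
            MaxPool1d(self.pool),
            Flatten(),
            Dense(self.n_filters * l_pool, self.hidden, self.rng),
            ReLU(),
            Dropout(self.dropout, self.rng),
            Dense(self.hidden, 1, self.rng),
        ])

    @property
    def conv_layer_count(self) -> int:
        return sum(isinstance(lay, Conv1d) for lay in self.net.layers)


class DLGWASNet(NumpyNet):
    """Two parallel conv branches at different scales, merged by addition."""

    def __init__(self, seed: int = 0, n_filters: int = 8, kernel_a: int = 4,
                 kernel_b: int = 20, pool: int = 2, hidden: int = 32,
                 lr: float | None = None):
        super().__init__(seed=seed, lr=lr)
        self.n_filters = n_filters
        self.kernel_a = kernel_a
        self.kernel_b = kernel_b
        self.pool = pool
        self.hidden = hidden

    def _prep(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != 4:
            raise ValueError(f"DLGWAS expects (n, 4, L) one-hot input, got {x.shape}")
        return x

    def build(self, input_shape):
        c, L = input_shape
        # 'same' padding keeps both branch outputs at length L for the add-up
        self.branch_a = Conv1d(c, self.n_filters, self.kernel_a, self.rng, padding="same")
        self.branch_b = Conv1d(c, self.n_filters, self.kernel_b, self.rng, padding="same")
        l_pool = L // self.pool
        self.head = Sequential([
            ReLU(),
            MaxPool1d(self.pool),
            Flatten(),
            Dense(self.n_filters * l_pool, self.hidden, self.rng),
            ReLU(),
            Dense(self.hidden, 1, self.rng),
        ])

    def parameters(self):
        return self.branch_a.params() + self.branch_b.params() + self.head.params()

    def net_forward(self, x, train):
        ya = self.branch_a.forward(x, train)
        yb = self.branch_b.forward(x, train)
        assert ya.shape == yb.shape  # add-up merge requires equal branch shapes
        return self.head.forward(ya + yb, train)

    def net_backward(self, g):
        gm = self.head.backward(g)
        self.branch_a.backward(gm)
        self.branch_b.backward(gm)


class DNNGPNet(NumpyNet):
    """Three stacked 1-D conv layers on the PCA score vector."""

    def __init__(self, seed: int = 0, channels: tuple[int, int, int] = (64, 32, 16),
                 kernel: int = 3, hidden: int = 64, dropout: float = 0.1,
                 lr: float | None = None):
        super().__init__(seed=seed, lr=lr)
        if len(channels) != 3:
            raise ValueError("DNNGP uses exactly three conv layers")
        self.channels = tuple(channels)
        self.kernel = kernel
        self.hidden = hidden
        self.dropout = dropout
        self._x_scale: np.ndarray | None = None

    def _prep(self, x):
        x = np.asarray(x, dtype=np.float64)
        if self._x_scale is None:
            # per-component scale, fixed from the first (training) batch seen
            scale = x.std(axis=0)
            self._x_scale = np.where(scale == 0.0, 1.0, scale)
        return (x / self._x_scale)[:, None, :]

    def build(self, input_shape):
        _, L = input_shape
        c1, c2, c3 = self.channels
        self.net = Sequential([
            Conv1d(1, c1, self.kernel, self.rng, padding="same"),
            ReLU(),
            Conv1d(c1, c2, self.kernel, self.rng, padding="same"),
            ReLU(),
            Conv1d(c2, c3, self.kernel, self.rng, padding="same"),
            ReLU(),
            Flatten(),
            Dense(c3 * L, self.hidden, self.rng),
            ReLU(),
            Dropout(self.dropout, self.rng),
            Dense(self.hidden, 1, self.rng),
        ])

    @property
    def conv_layer_count(self) -> int:
        return sum(isinstance(lay, Conv1d) for lay in self.net.layers)

    @property
    def dropout_layer_count(self) -> int:
        return sum(isinstance(lay, Dropout) for lay in self.net.layers)

    def _extra_state(self):
        return {"x_scale": self._x_scale}

    def _set_extra_state(self, extra):
        self._x_scale = extra.get("x_scale")


class SoyDNGPNet(NumpyNet):
    """VGG-style 2-D CNN over the square one-hot genotype image."""

    def __init__(self, seed: int = 0, base_channels: int = 32, n_blocks: int = 1,
                 hidden: int = 128, lr: float | None = None):
        super().__init__(seed=seed, lr=lr)
        self.base_channels = base_channels
        self.n_blocks = n_blocks
        self.hidden = hidden

    def _prep(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"SoyDNGP expects (n, 3, S, S) input, got {x.shape}")
        return x

    @property
    def channel_schedule(self) -> list[int]:
        # channels double per block regardless of spatial size
        return [self.base_channels * 2**i for i in range(self.n_blocks)]

    def build(self, input_shape):
        c, s, s2 = input_shape
        if s != s2:
            raise ValueError("SoyDNGP input must be square")
        layers: list = []
        c_in = c
        size = s
        for c_out in self.channel_schedule:
            layers += [Conv2d(c_in, c_out, 3, self.rng, pad=1), ReLU(), MaxPool2d()]
            c_in = c_out
            size = (size + 1) // 2  # ceil pooling
        layers += [Flatten(), Dense(c_in * size * size, self.hidden, self.rng),
                   ReLU(), Dense(self.hidden, 1, self.rng)]
        self.net = Sequential(layers)
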