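"""Environment-gated CNN: a 1-D conv backbone over the dosage vector whose
feature maps are reweighted channel-wise by gates derived from an
environment feature vector (squeeze-and-excitation style).

The environment branch is an MLP embedding the environment vector into 64
dimensions; a learned linear map plus sigmoid turns the embedding into one
gate in (0, 1) per conv channel.  With every gate pinned to 1 the network
is exactly the genotype-only backbone.
"""

from __future__ import annotations

import numpy as np

from autogs.models.nn import (
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    MaxPool1d,
    NumpyNet,
    ReLU,
    Sequential,
    Sigmoid,
)


class EnvSENet(NumpyNet):
    """fit/predict on (x_geno, x_env) tuples."""

    def __init__(self, seed: int = 0, n_filters: int = 8, kernel: int = 18,
                 pool: int = 2, hidden: int = 32, dropout: float = 0.05,
                 embed_dim: int = 64, lr: float | None = None):
        super().__init__(seed=seed, lr=lr)
        self.n_filters = n_filters
        self.kernel = kernel
        self.pool = pool
        self.hidden = hidden
        self.dropout = dropout
        self.embed_dim = embed_dim
        self.gate_override: float | None = None  # set to 1.0 to bypass gating

    def _prep(self, x):
        if not (isinstance(x, tuple) and len(x) == 2):
            raise ValueError("EnvSE expects (genotype, environment) input tuple")
        xg, xe = x
        xg = np.asarray(xg, dtype=np.float64)
        xe = np.asarray(xe, dtype=np.float64)
        if xg.shape[0] != xe.shape[0]:
            raise ValueError("genotype and environment batches differ in length")
        return ((xg - 1.0)[:, None, :], xe)

    def build(self, input_shape):
        # input_shape = ((1, L), (env_dim,)) from the prepped input tuple
        (geno_shape, env_shape) = input_shape
        _, L = geno_shape
        self.env_dim = int(env_shape[0])
        l_conv = L - self.kernel + 1
        l_pool = l_conv // self.pool
        self.conv = Conv1d(1, self.n_filters, self.kernel, self.rng)
        self.conv_act = ReLU()
        self.env_mlp = Sequential([
            Dense(self.env_dim, self.embed_dim, self.rng),
            ReLU(),
        ])
        self.gate_map = Dense(self.embed_dim, self.n_filters, self.rng)
        self.gate_act = Sigmoid()
        self.head = Sequential([
            MaxPool1d(self.pool),
            Flatten(),
            Dense(self.n_filters * l_pool, self.hidden, self.rng),
            ReLU(),
            Dropout(self.dropout, self.rng),
            Dense(self.hidden, 1, self.rng),
        ])

    def parameters(self):
        return (
            self.conv.params()
            + self.env_mlp.params()
            + self.gate_map.params()
            + self.head.params()
        )

    def net_forward(self, x, train):
        xg, xe = x
        h = self.conv_act.forward(self.conv.forward(xg, train), train)
        if self.gate_override is not None:
            self._gates = None
            h = h * self.gate_override
        else:
            if xe.shape[1] != self.env_dim:
                raise ValueError(
                    f"environment vector length {xe.shape[1]} != fitted length {self.env_dim}"
                )
            emb = self.env_mlp.forward(xe, train)  # (n, 64)
            gates = self.gate_act.forward(self.gate_map.forward(emb, train), train)
            self._gates = gates
            self._h = h
            h = h * gates[:, :, None]
        return self.head.forward(h, train)

    def net_backward(self, g):
        gh = self.head.backward(g)
        if self._gates is None:
            if self.gate_override is not None:
                gh = gh * self.gate_override
        else:
            dgates = (gh * self._h).sum(axis=2)  # (n, C)
            self.env_mlp.backward(self.gate_map.backward(self.gate_act.backward(dgates)))
            gh = gh * self._gates[:, :, None]
        self.conv.backward(self.conv_act.backward(gh))

    def backbone_forward(self, x_geno) -> np.ndarray:
        """Eval-mode prediction ignoring the environment branch (gates = 1)."""
        saved, self.gate_override = self.gate_override, 1.0
        try:
            dummy_env = np.zeros((np.asarray(x_geno).shape[0], self.env_dim))
            out = self.predict((x_geno, dummy_env))
        finally:
            self.gate_override = saved
        return out
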