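"""The FASPP-GRU gesture classifier and the CNN-LSTM baseline.

Both consume windows of padded 16 x 16 voltage matrices, shape
``(B, T, 16, 16)`` with T = 11 frames (480 ms at 23 fps), and emit
9-class probabilities.

FASPP-GRU per frame: bilinear x2 upsample -> fold (space-to-depth) ->
atrous spatial pyramid (1x1 branch + dilated 3x3 branches at rates
1/2/4, concatenated and projected) -> unfold (depth-to-space) -> coarse
average-pool grid flattened to a frame embedding; a single-layer GRU
consumes the 11 embeddings and an MLP head classifies its final hidden
state.  Default widths are chosen to land the trainable parameter count
on the 0.65M budget; the CNN-LSTM baseline (two conv/pool stages, LSTM,
MLP head) lands on its 0.88M budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from eitgest.nn import core
from eitgest.nn.core import (
    AvgPool2d,
    BilinearUpsample2x,
    Conv2d,
    Flatten,
    Fold,
    GRU,
    LSTM,
    Linear,
    ReLU,
    Unfold,
    softmax,
)


@dataclass
class FASPPGRUConfig:
    """Architecture and training hyperparameters of FASPP-GRU.

    ``mlp_hidden`` is set so the total trainable parameter count is
    650k to within 0.01M.
    """

    grid: int = 16
    upsample_factor: int = 2
    aspp_dilations: tuple = (1, 2, 4)
    aspp_channels: int = 8
    proj_channels: int = 16
    pool_window: int = 4
    embed_dim: int = 64
    gru_hidden: int = 128
    mlp_hidden: int = 4043
    n_classes: int = 9
    learning_rate: float = 5e-5
    batch_size: int = 64
    max_epochs: int = 150
    patience: int = 15
    seed: int = 0


@dataclass
class CNNLSTMConfig:
    """CNN-LSTM baseline mirrored onto the 0.88M parameter budget."""

    grid: int = 16
    conv_channels: tuple = (8, 16)
    embed_dim: int = 64
    lstm_hidden: int = 128
    mlp_hidden: int = 5532
    n_classes: int = 9
    learning_rate: float = 5e-5
    batch_size: int = 64
    max_epochs: int = 150
    patience: int = 15
    seed: int = 0


class _SequenceClassifier:
    """Shared plumbing: parameter bookkeeping, prediction, checkpoints."""

    cfg = None

    def params(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=core.DTYPE)
        out = []
        for s in range(0, len(X), batch_size):
            out.append(softmax(self.forward(X[s : s + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(X, batch_size).argmax(axis=1)

    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights):
            p.value[...] = w

    def save(self, path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(path, config=json.dumps(asdict(self.cfg)), **arrays)

    @classmethod
    def load(cls, path):
        data = np.load(path, allow_pickle=False)
        fields = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in json.loads(str(data["config"])).items()
        }
        cfg = cls.config_cls(**fields)
        model = cls(cfg)
        model.set_weights([data[f"p{i}"] for i in range(len(model.params()))])
        return model


class FASPPGRU(_SequenceClassifier):
    config_cls = FASPPGRUConfig

    def __init__(self, cfg: FASPPGRUConfig | None = None):
        self.cfg = cfg = cfg or FASPPGRUConfig()
        rng = np.random.default_rng(cfg.seed)
        g2 = cfg.grid * cfg.upsample_factor  # 32
        self.upsample = BilinearUpsample2x(cfg.grid)
        self.fold = Fold()
        c_in = 4  # 1 channel folded 2x2
        self.branch_1x1 = Conv2d(c_in, cfg.aspp_channels, 1, rng)
        self.branches = [
            Conv2d(c_in, cfg.aspp_channels, 3, rng, dilation=d)
            for d in cfg.aspp_dilations
        ]
        n_branches = 1 + len(cfg.aspp_dilations)
        self.relu_branches = [ReLU() for _ in range(n_branches)]
        self.proj = Conv2d(n_branches * cfg.aspp_channels, cfg.proj_channels, 1, rng)
        self.relu_proj = ReLU()
        self.unfold = Unfold()
        self.pool = AvgPool2d(cfg.pool_window)
        self.flatten = Flatten()
        n_flat = (cfg.proj_channels // 4) * (g2 // cfg.pool_window) ** 2
        self.embed = Linear(n_flat, cfg.embed_dim, rng)
        self.relu_embed = ReLU()
        self.gru = GRU(cfg.embed_dim, cfg.gru_hidden, rng)
        self.head1 = Linear(cfg.gru_hidden, cfg.mlp_hidden, rng)
        self.relu_head = ReLU()
        self.head2 = Linear(cfg.mlp_hidden, cfg.n_classes, rng)

    def _all_layers(self):
        return [
            self.branch_1x1,
            *self.branches,
            self.proj,
            self.embed,
            self.gru,
            self.head1,
            self.head2,
        ]

    def frame_encoder(self, frames: np.ndarray, train: bool = False) -> np.ndarray:
        """Spatial encoding of a stack of frames ``(N, 16, 16) -> (N, d)``."""
        x = frames[:, None]  # (N, 1, 16, 16)
        x = self.upsample.forward(x, train)
        x = self.fold.forward(x, train)
        outs = [self.relu_branches[0].forward(self.branch_1x1.forward(x, train), train)]
        for conv, relu in zip(self.branches, self.relu_branches[1:]):
            outs.append(relu.forward(conv.forward(x, train), train))
        cat = np.concatenate(outs, axis=1)
        self._split = np.cumsum([o.shape[1] for o in outs])[:-1]
        y = self.relu_proj.forward(self.proj.forward(cat, train), train)
        y = self.unfold.forward(y, train)
        y = self.pool.forward(y, train)
        y = self.flatten.forward(y, train)
        y = self.relu_embed.forward(self.embed.forward(y, train), train)
        return y

    def _frame_encoder_backward(self, g):
        g = self.embed.backward(self.relu_embed.backward(g))
        g = self.flatten.backward(g)
        g = self.pool.backward(g)
        g = self.unfold.backward(g)
        g = self.proj.backward(self.relu_proj.backward(g))
        parts = np.split(g, self._split, axis=1)
        gx = self.branch_1x1.backward(self.relu_branches[0].backward(parts[0]))
        for conv, relu, part in zip(self.branches, self.relu_branches[1:], parts[1:]):
            gx = gx + conv.backward(relu.backward(part))
        gx = self.fold.backward(gx)
        gx = self.upsample.backward(gx)
        return gx[:, 0]

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=core.DTYPE)
        B, T = X.shape[:2]
        emb = self.frame_encoder(X.reshape(B * T, *X.shape[2:]), train)
        h = self.gru.forward(emb.reshape(B, T, -1), train)
        z = self.relu_head.forward(self.head1.forward(h, train), train)
        return self.head2.forward(z, train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head2.backward(dlogits)
        g = self.head1.backward(self.relu_head.backward(g))
        g = self.gru.backward(g)
        B, T, d = g.shape
        self._frame_encoder_backward(g.reshape(B * T, d))

    def embeddings(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Final GRU hidden states (feature space used for UMAP plots)."""
        X = np.asarray(X, dtype=core.DTYPE)
        out = []
        for s in range(0, len(X), batch_size):
            xb = X[s : s + batch_size]
            B, T = xb.shape[:2]
            emb = self.frame_encoder(xb.reshape(B * T, *xb.shape[2:]), False)
            out.append(self.gru.forward(emb.reshape(B, T, -1), False))
        return np.concatenate(out, axis=0)


class CNNLSTM(_SequenceClassifier):
    config_cls = CNNLSTMConfig

    def __init__(self, cfg: CNNLSTMConfig | None = None):
        self.cfg = cfg = cfg or CNNLSTMConfig()
        rng = np.random.default_rng(cfg.seed)
        c1, c2 = cfg.conv_channels
        self.conv1 = Conv2d(1, c1, 3, rng)
        self.relu1 = ReLU()
        self.pool1 = AvgPool2d(2)
        self.conv2 = Conv2d(c1, c2, 3, rng)
        self.relu2 = ReLU()
        self.pool2 = AvgPool2d(2)
        self.flatten = Flatten()
        n_flat = c2 * (cfg.grid // 4) ** 2
        self.embed = Linear(n_flat, cfg.embed_dim, rng)
        self.relu_embed = ReLU()
        self.lstm = LSTM(cfg.embed_dim, cfg.lstm_hidden, rng)
        self.head1 = Linear(cfg.lstm_hidden, cfg.mlp_hidden, rng)
        self.relu_head = ReLU()
        self.head2 = Linear(cfg.mlp_hidden, cfg.n_classes, rng)

    def _all_layers(self):
        return [self.conv1, self.conv2, self.embed, self.lstm, self.head1, self.head2]

    def frame_encoder(self, frames: np.ndarray, train: bool = False) -> np.ndarray:
        x = frames[:, None]
        x = self.pool1.forward(self.relu1.forward(self.conv1.forward(x, train), train), train)
        x = self.pool2.forward(self.relu2.forward(self.conv2.forward(x, train), train), train)
        x = self.flatten.forward(x, train)
        return self.relu_embed.forward(self.embed.forward(x, train), train)

    def _frame_encoder_backward(self, g):
        g = self.embed.backward(self.relu_embed.backward(g))
        g = self.flatten.backward(g)
        g = self.conv2.backward(self.relu2.backward(self.pool2.backward(g)))
        g = self.conv1.backward(self.relu1.backward(self.pool1.backward(g)))
        return g[:, 0]

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=core.DTYPE)
        B, T = X.shape[:2]
        emb = self.frame_encoder(X.reshape(B * T, *X.shape[2:]), train)
        h = self.lstm.forward(emb.reshape(B, T, -1), train)
        z = self.relu_head.forward(self.head1.forward(h, train), train)
        return self.head2.forward(z, train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head2.backward(dlogits)
        g = self.head1.backward(self.relu_head.backward(g))
        g = self.lstm.backward(g)
        B, T, d = g.shape
        self._frame_encoder_backward(g.reshape(B * T, d))

    def embeddings(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=core.DTYPE)
        out = []
        for s in range(0, len(X), batch_size):
            xb = X[s : s + batch_size]
            B, T = xb.shape[:2]
            emb = self.frame_encoder(xb.reshape(B * T, *xb.shape[2:]), False)
            out.append(self.lstm.forward(emb.reshape(B, T, -1), False))
        return np.concatenate(out, axis=0)
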