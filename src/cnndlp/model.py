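"""The dual-branch pair scorer.

Left branch: the attention-enhanced embedding X_hat goes through two
convolution (2x2, 16 then 32 filters, one ring of zero padding, batch
normalization) + max-pooling blocks, a fully connected layer and a 2-way
softmax; the class-1 probability is ``score_left``. The attention
parameters are trained jointly with the branch.

Right branch: the embedding Y feeds a convolutional autoencoder (two
conv+pool encoder layers, mirrored max-unpool + transpose-conv decoder
layers restoring the input shape exactly, via the recorded pooling argmax
positions). The flattened code also feeds a fully connected + softmax
classifier giving ``score_right``. The branch is trained on the sum of the
classification cross-entropy and the reconstruction loss.

The final association score is the convex combination
``lambda * score_left + (1 - lambda) * score_right``.

Training uses Adam (lr 1e-3), batch size 32, up to ``epochs`` epochs with
early stopping when the training loss plateaus, dropout 0.5 on the fully
connected inputs; all randomness flows from one seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import _nn

__all__ = [
    "ModelConfig",
    "PairScore",
    "conv_pool_block",
    "reconstruction_loss",
    "classification_loss",
    "fuse_scores",
    "DualModel",
]

_EPS = 1e-12


@dataclasses.dataclass
class ModelConfig:
    """Hyperparameters of the scorer and its training loop."""

    conv_window: tuple[int, int] = (2, 2)
    pool_window: tuple[int, int] = (2, 2)
    nconv1: int = 16
    nconv2: int = 32
    encoder_depth: int = 2
    decoder_depth: int = 2
    nencode: tuple[int, int] = (16, 32)
    ndecode: tuple[int, int] = (16, 1)
    d_att: int = 8
    alpha: float = 0.9
    beta: float = 0.8
    lam: float = 0.3
    dropout: float = 0.5
    input_dropout: float = 0.3
    batchnorm: bool = True
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    patience: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        self.conv_window = tuple(self.conv_window)  # type: ignore[assignment]
        self.pool_window = tuple(self.pool_window)  # type: ignore[assignment]
        if min(self.conv_window) < 1 or min(self.pool_window) < 1:
            raise ValueError("window sizes must be >= 1")
        if self.pool_window != (2, 2):
            raise ValueError("only 2x2 pooling windows are supported")
        for w, name in ((self.alpha, "alpha"), (self.beta, "beta"), (self.lam, "lambda")):
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {w}")
        if not 0.0 <= self.input_dropout < 1.0:
            raise ValueError("input_dropout must be in [0, 1)")
        if min(self.nconv1, self.nconv2, self.d_att) < 1:
            raise ValueError("filter counts and d_att must be >= 1")
        if self.encoder_depth != 2 or self.decoder_depth != 2:
            raise ValueError("the architecture uses two encoder and two decoder layers")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conv_window"] = list(self.conv_window)
        d["pool_window"] = list(self.pool_window)
        d["nencode"] = list(self.nencode)
        d["ndecode"] = list(self.ndecode)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclasses.dataclass
class PairScore:
    """Scores of one pair; the fused score is lambda-weighted by contract."""

    score_left: float
    score_right: float
    score: float
    label: int

    def __post_init__(self) -> None:
        for s in (self.score_left, self.score_right, self.score):
            if not 0.0 <= s <= 1.0:
                raise ValueError("scores must lie in [0, 1]")


def conv_pool_block(
    x: np.ndarray,
    filters: np.ndarray,
    bias: np.ndarray,
    pool: tuple[int, int] = (2, 2),
) -> tuple[np.ndarray, np.ndarray]:
    """One convolution + relu + max-pool block, functional form.

    ``x`` is (B, C, H, W); ``filters`` is (F, C, w, h). The input is padded
    with one ring of zeros, convolved (valid, stride 1), relu-activated,
    then max-pooled with non-overlapping ``pool`` windows (ceil mode).
    Returns ``(Z, V)``: the pre-pool feature maps of shape
    (B, F, H+3-w, W+3-h) and the pooled maps.
    """
    if pool != (2, 2):
        raise ValueError("only 2x2 pooling windows are supported")
    x = np.atleast_2d(np.asarray(x, float))
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    kh, kw = filters.shape[2], filters.shape[3]
    if x.shape[2] + 2 < kh or x.shape[3] + 2 < kw:
        raise ValueError("input smaller than convolution window after padding")
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    z = _nn.conv2d(xp, filters) + bias[None, :, None, None]
    z = np.maximum(z, 0.0)
    pool_layer = _nn.MaxPool()
    v = pool_layer.forward(z, train=False)
    return z, v


def reconstruction_loss(Y: np.ndarray, Y_rec: np.ndarray) -> float:
    """Mean over samples of the per-sample sum of squared residuals."""
    Y, Y_rec = np.asarray(Y, float), np.asarray(Y_rec, float)
    if Y.shape != Y_rec.shape:
        raise ValueError(f"shape mismatch {Y.shape} vs {Y_rec.shape}")
    if Y.ndim == 2:
        Y, Y_rec = Y[None], Y_rec[None]
    t = Y.shape[0]
    return float(((Y - Y_rec) ** 2).reshape(t, -1).sum(axis=1).mean())


def classification_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Summed binary cross-entropy; probabilities clamped at 1e-12."""
    s = np.clip(np.asarray(scores, float), _EPS, 1.0 - _EPS)
    y = np.asarray(labels, float)
    return float(-(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)).sum())


def fuse_scores(score_left, score_right, lam: float):
    """Weighted sum lambda*score_left + (1-lambda)*score_right."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return lam * np.asarray(score_left, float) + (1.0 - lam) * np.asarray(
        score_right, float
    )


class _LeftBranch:
    def __init__(self, n_cols: int, cfg: ModelConfig, rng: np.random.Generator):
        k = cfg.conv_window
        self.att = _nn.Attention(cfg.d_att, rng)
        self.conv1 = _nn.Conv(1, cfg.nconv1, k, rng)
        self.bn1 = _nn.BatchNorm(cfg.nconv1) if cfg.batchnorm else None
        self.relu1 = _nn.ReLU()
        self.pool1 = _nn.MaxPool()
        self.conv2 = _nn.Conv(cfg.nconv1, cfg.nconv2, k, rng)
        self.bn2 = _nn.BatchNorm(cfg.nconv2) if cfg.batchnorm else None
        self.relu2 = _nn.ReLU()
        self.pool2 = _nn.MaxPool()
        self.flat = _nn.Flatten()
        self.drop = _nn.Dropout(cfg.dropout, rng)
        flat_dim = _flat_dim_after_two_blocks(2, n_cols, k, cfg.nconv2)
        self.dense = _nn.Dense(flat_dim, 2, rng)
        self.layers = [
            l
            for l in (
                self.att,
                self.conv1,
                self.bn1,
                self.relu1,
                self.pool1,
                self.conv2,
                self.bn2,
                self.relu2,
                self.pool2,
                self.flat,
                self.drop,
                self.dense,
            )
            if l is not None
        ]

    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        h = self.att.forward(X, train)
        h = h[:, None, :, :]  # channel axis
        for layer in self.layers[1:]:
            h = layer.forward(h, train)
        if not np.isfinite(h).all():
            raise FloatingPointError("non-finite activations in left branch")
        return h

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers[1:]):
            g = layer.backward(g)
        self.att.backward(g[:, 0])


class _RightBranch:
    def __init__(self, n_cols: int, cfg: ModelConfig, rng: np.random.Generator):
        k = cfg.conv_window
        ne1, ne2 = cfg.nencode
        self.conv1 = _nn.Conv(1, ne1, k, rng)
        self.relu1 = _nn.ReLU()
        self.pool1 = _nn.MaxPool()
        self.conv2 = _nn.Conv(ne1, ne2, k, rng)
        self.relu2 = _nn.ReLU()
        self.pool2 = _nn.MaxPool()
        self.unpool2 = _nn.MaxUnpool(self.pool2)
        self.tconv2 = _nn.TransposeConv(ne2, cfg.ndecode[0], k, rng)
        self.relu_d = _nn.ReLU()
        self.unpool1 = _nn.MaxUnpool(self.pool1)
        self.tconv1 = _nn.TransposeConv(cfg.ndecode[0], cfg.ndecode[1], k, rng)
        self.flat = _nn.Flatten()
        self.drop = _nn.Dropout(cfg.dropout, rng)
        flat_dim = _flat_dim_after_two_blocks(2, n_cols, k, ne2)
        self.dense = _nn.Dense(flat_dim, 2, rng)
        self.layers = [
            self.conv1,
            self.relu1,
            self.pool1,
            self.conv2,
            self.relu2,
            self.pool2,
            self.unpool2,
            self.tconv2,
            self.relu_d,
            self.unpool1,
            self.tconv1,
            self.flat,
            self.drop,
            self.dense,
        ]

    def encode(self, Y: np.ndarray, train: bool) -> np.ndarray:
        h = Y[:, None, :, :]
        for layer in (self.conv1, self.relu1, self.pool1, self.conv2, self.relu2, self.pool2):
            h = layer.forward(h, train)
        return h

    def decode(self, code: np.ndarray, train: bool) -> np.ndarray:
        h = code
        for layer in (self.unpool2, self.tconv2, self.relu_d, self.unpool1, self.tconv1):
            h = layer.forward(h, train)
            if h.ndim != 4:
                raise RuntimeError(f"shape lost at decoder stage {type(layer).__name__}")
        return h[:, 0]

    def forward(self, Y: np.ndarray, train: bool):
        code = self.encode(Y, train)
        y_rec = self.decode(code, train)
        if y_rec.shape != Y.shape:
            raise RuntimeError(
                f"decoder output shape {y_rec.shape} != encoder input {Y.shape}"
            )
        h = self.flat.forward(code, train)
        h = self.drop.forward(h, train)
        logits = self.dense.forward(h, train)
        if not np.isfinite(logits).all() or not np.isfinite(y_rec).all():
            raise FloatingPointError("non-finite activations in right branch")
        return logits, y_rec, code

    def backward(self, g_logits: np.ndarray, g_rec: np.ndarray) -> None:
        # Classifier-head path into the code.
        g = self.dense.backward(g_logits)
        g = self.drop.backward(g)
        g_code_head = self.flat.backward(g)
        # Reconstruction path back through the decoder into the code.
        g = g_rec[:, None, :, :]
        for layer in (self.tconv1, self.unpool1, self.relu_d, self.tconv2, self.unpool2):
            g = layer.backward(g)
        g_code = g_code_head + g
        for layer in (self.pool2, self.relu2, self.conv2, self.pool1, self.relu1, self.conv1):
            g_code = layer.backward(g_code)


def _flat_dim_after_two_blocks(h: int, w: int, k: tuple[int, int], channels: int) -> int:
    kh, kw = k
    for _ in range(2):
        h, w = h + 3 - kh, w + 3 - kw  # pad 1, valid conv
        h, w = -(-h // 2), -(-w // 2)  # ceil-mode 2x2 pool
    return channels * h * w


class DualModel:
    """Trainable dual-branch scorer over fixed-width pair embeddings."""

    def __init__(self, n_cols: int, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.n_cols = n_cols
        self.rng = np.random.default_rng(self.config.seed)
        self.left = _LeftBranch(n_cols, self.config, self.rng)
        self.right = _RightBranch(n_cols, self.config, self.rng)
        self.opt_left = _nn.Adam(self.left.layers, lr=self.config.learning_rate)
        self.opt_right = _nn.Adam(self.right.layers, lr=self.config.learning_rate)
        self.history: list[dict[str, float]] = []

    # -- training ---------------------------------------------------------

    def train_step(self, X: np.ndarray, Y: np.ndarray, labels: np.ndarray) -> dict:
        logits = self.left.forward(X, train=True)
        _, loss_l, grad = _nn.softmax_xent(logits, labels)
        self.left.backward(grad)
        self.opt_left.step()

        logits_r, y_rec, _ = self.right.forward(Y, train=True)
        _, loss_r, grad_r = _nn.softmax_xent(logits_r, labels)
        loss_auto = reconstruction_loss(Y, y_rec)
        g_rec = 2.0 * (y_rec - Y) / len(Y)
        self.right.backward(grad_r, g_rec)
        self.opt_right.step()
        return {"loss_left": loss_l, "loss_right": loss_r, "loss_auto": loss_auto}

    def fit(self, X: np.ndarray, Y: np.ndarray, labels: np.ndarray) -> "DualModel":
        """Train both branches; early-stops when the epoch loss plateaus.

        Besides the dropout on the fully connected inputs, embedding entries
        are dropped at rate ``input_dropout`` during training (inverted
        scaling); with a few hundred training pairs and this capacity the
        model memorizes whole similarity profiles otherwise.
        """
        cfg = self.config
        n = len(labels)
        best, since_best = np.inf, 0
        keep = 1.0 - cfg.input_dropout
        for _epoch in range(cfg.epochs):
            order = self.rng.permutation(n)
            totals = {"loss_left": 0.0, "loss_right": 0.0, "loss_auto": 0.0}
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                if len(idx) < 2:
                    continue  # batchnorm needs more than one sample
                xb, yb = X[idx], Y[idx]
                if cfg.input_dropout > 0:
                    xb = xb * (self.rng.random(xb.shape) < keep) / keep
                    yb = yb * (self.rng.random(yb.shape) < keep) / keep
                step = self.train_step(xb, yb, labels[idx])
                for key, val in step.items():
                    totals[key] += val
                n_batches += 1
            epoch_loss = sum(totals.values()) / max(n_batches, 1)
            self.history.append({k: v / max(n_batches, 1) for k, v in totals.items()})
            if epoch_loss < best - 1e-4:
                best, since_best = epoch_loss, 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        self._recalibrate_batchnorm(X)
        return self

    def _recalibrate_batchnorm(self, X: np.ndarray, batch_size: int = 256) -> None:
        """Refresh batch-norm running statistics with a clean training pass.

        During training the normalization statistics accumulate over
        dropout-corrupted inputs; inference sees uncorrupted embeddings, so
        the stored statistics are re-estimated once on the clean inputs.
        """
        bns = [l for l in self.left.layers if isinstance(l, _nn.BatchNorm)]
        if not bns or len(X) < 2:
            return
        for bn in bns:
            bn.start_collect()
        rate = self.left.drop.rate
        self.left.drop.rate = 0.0
        try:
            for start in range(0, len(X), batch_size):
                xb = X[start : start + batch_size]
                if len(xb) >= 2:
                    self.left.forward(xb, train=True)
        finally:
            self.left.drop.rate = rate
            for bn in bns:
                bn.finish_collect()

    # -- inference --------------------------------------------------------

    def score(
        self, X: np.ndarray, Y: np.ndarray, batch_size: int = 512
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Deterministic forward pass; returns (left, right, fused) scores."""
        lefts, rights = [], []
        for start in range(0, len(X), batch_size):
            xb, yb = X[start : start + batch_size], Y[start : start + batch_size]
            logits = self.left.forward(xb, train=False)
            lefts.append(_nn.softmax(logits, axis=-1)[:, 1])
            # scoring needs only the encoder + classifier head, not the decoder
            code = self.right.encode(yb, train=False)
            h = self.right.flat.forward(code, train=False)
            h = self.right.drop.forward(h, train=False)
            logits_r = self.right.dense.forward(h, train=False)
            rights.append(_nn.softmax(logits_r, axis=-1)[:, 1])
        sl, sr = np.concatenate(lefts), np.concatenate(rights)
        return sl, sr, fuse_scores(sl, sr, self.config.lam)

    # -- persistence ------------------------------------------------------

    def _param_layers(self) -> dict[str, "_nn.Layer"]:
        named = {}
        for side, branch in (("left", self.left), ("right", self.right)):
            for i, layer in enumerate(branch.layers):
                if layer.params:
                    named[f"{side}.{i}.{type(layer).__name__}"] = layer
        return named

    def save(self, path: str | Path) -> None:
        arrays = {}
        for name, layer in self._param_layers().items():
            for pi, p in enumerate(layer.params):
                arrays[f"{name}.{pi}"] = p
            if isinstance(layer, _nn.BatchNorm):
                arrays[f"{name}.run_mean"] = layer.run_mean
                arrays[f"{name}.run_var"] = layer.run_var
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"n_cols": self.n_cols, "config": self.config.to_dict()}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DualModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(meta["n_cols"], ModelConfig.from_dict(meta["config"]))
        with np.load(path.with_suffix(".npz")) as data:
            for name, layer in model._param_layers().items():
                for pi, p in enumerate(layer.params):
                    p[...] = data[f"{name}.{pi}"]
                if isinstance(layer, _nn.BatchNorm):
                    layer.run_mean = data[f"{name}.run_mean"]
                    layer.run_var = data[f"{name}.run_var"]
        return model
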