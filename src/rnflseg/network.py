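"""RNFL-Net: a customized U-Net for three-category RNFL segmentation.

The encoder has four blocks of (conv3-BN-ReLU x2 + dropout 0.1) with
filter widths 32, 64, 128, 256 and 2x2 max pooling between levels; the
bottleneck carries 512 filters (16x the initial width); the decoder
mirrors the encoder with stride-2 upconvolutions that halve the channel
count, concatenation with the same-level encoder feature map, and two
conv3-BN-ReLU stages per block.  A final 1x1 convolution maps the 32
remaining channels to the three classes through a per-channel sigmoid —
the output is therefore *not* a partition of unity and is decoded by
per-pixel argmax.  Training uses a soft Dice loss averaged over the
three classes and Adam starting at 1e-4 with reduce-on-plateau decay
floored at 1e-6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from rnflseg import nn
from rnflseg.metrics import dice as dice_metric
from rnflseg.types import RNFL

EPSILON = 1e-6


@dataclass
class NetConfig:
    """Architecture and optimization constants.

    Invariants: encoder filter widths are ``initial_filters * 2**level``
    and the bottleneck is 16x the initial width; the decoder mirrors the
    encoder.  Sigmoid output (not softmax) is deliberate, so per-pixel
    channel scores need not sum to 1.
    """

    input_shape: tuple[int, int, int] = (128, 128, 1)
    n_classes: int = 3
    encoder_depth: int = 4
    initial_filters: int = 32
    bottleneck_filters: int = 512
    kernel_size: int = 3
    dropout_rate: float = 0.1
    lr_initial: float = 1e-4
    lr_floor: float = 1e-6
    lr_decay_factor: float = 0.5
    lr_patience: int = 10
    batch_size: int = 16
    epochs: int = 150

    def validate(self) -> None:
        if self.bottleneck_filters != 16 * self.initial_filters:
            raise ValueError(
                "bottleneck_filters must be 16 x initial_filters "
                f"({16 * self.initial_filters}), got {self.bottleneck_filters}"
            )
        if self.kernel_size != 3:
            raise ValueError("kernel_size is fixed at 3 in this architecture")
        if self.encoder_depth != 4:
            raise ValueError("encoder_depth is fixed at 4 blocks")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        h, w, c = self.input_shape
        factor = 2**self.encoder_depth
        if h % factor or w % factor or h < 32 or w < 32:
            raise ValueError(
                f"input H and W must be multiples of {factor} and >= 32"
            )

    @property
    def encoder_filters(self) -> list[int]:
        return [self.initial_filters * 2**i for i in range(self.encoder_depth)]


class RNFLNet:
    """The network graph with explicit forward/backward passes."""

    def __init__(self, config: NetConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        f = config.encoder_filters

        def conv_block(c_in, c_out, dropout):
            layers = [
                nn.Conv3x3(c_in, c_out, rng), nn.BatchNorm(c_out), nn.ReLU(),
                nn.Conv3x3(c_out, c_out, rng), nn.BatchNorm(c_out), nn.ReLU(),
            ]
            if dropout:
                layers.append(nn.Dropout(config.dropout_rate, self._dropout_rng))
            return layers

        self.encoder = []
        c_prev = config.input_shape[2]
        for c_out in f:
            self.encoder.append(conv_block(c_prev, c_out, dropout=True))
            c_prev = c_out
        self.pools = [nn.MaxPool2() for _ in f]
        self.bottleneck = conv_block(c_prev, config.bottleneck_filters, dropout=False)

        self.upconvs = []
        self.decoder = []
        c_prev = config.bottleneck_filters
        for c_out in reversed(f):
            self.upconvs.append(nn.UpConv2x2(c_prev, c_out, rng))
            self.decoder.append(conv_block(2 * c_out, c_out, dropout=False))
            c_prev = c_out
        self.final = nn.Conv1x1(f[0], config.n_classes, rng)

    # -- introspection used by the architecture audit ---------------------
    @property
    def conv_layers(self) -> list:
        """All weighted conv-type layers in forward order."""
        out = []
        for block in self.encoder:
            out += [l for l in block if isinstance(l, nn.Conv3x3)]
        out += [l for l in self.bottleneck if isinstance(l, nn.Conv3x3)]
        for up, block in zip(self.upconvs, self.decoder):
            out.append(up)
            out += [l for l in block if isinstance(l, nn.Conv3x3)]
        out.append(self.final)
        return out

    def params(self) -> list[nn.Param]:
        out = []
        for layer in self._all_layers():
            out += layer.params()
        return out

    def _all_layers(self):
        for block in self.encoder:
            yield from block
        yield from self.pools
        yield from self.bottleneck
        for up, block in zip(self.upconvs, self.decoder):
            yield up
            yield from block
        yield self.final

    # -- passes -----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """x: (N, 1, H, W) float32 -> sigmoid probabilities (N, K, H, W)."""
        skips = []
        h = x
        for block, pool in zip(self.encoder, self.pools):
            for layer in block:
                h = layer.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        for layer in self.bottleneck:
            h = layer.forward(h, training)
        for up, block, skip in zip(self.upconvs, self.decoder, reversed(skips)):
            h = up.forward(h, training)
            h = np.concatenate([skip, h], axis=1)
            for layer in block:
                h = layer.forward(h, training)
        logits = self.final.forward(h, training)
        self._probs = nn.sigmoid(logits)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the sigmoid probabilities."""
        d = dprobs * self._probs * (1.0 - self._probs)
        d = self.final.backward(d)
        skip_grads = []
        for up, block in zip(reversed(self.upconvs), reversed(self.decoder)):
            for layer in reversed(block):
                d = layer.backward(d)
            c_skip = d.shape[1] // 2
            skip_grads.append(d[:, :c_skip])
            d = up.backward(d[:, c_skip:])
        for layer in reversed(self.bottleneck):
            d = layer.backward(d)
        for block, pool, dskip in zip(
            reversed(self.encoder), reversed(self.pools), reversed(skip_grads)
        ):
            d = pool.backward(d) + dskip
            for layer in reversed(block):
                d = layer.backward(d)

    # -- persistence ------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        bns = [l for l in self._all_layers() if isinstance(l, nn.BatchNorm)]
        for i, bn in enumerate(bns):
            arrays[f"bn{i}_mean"] = bn.running_mean
            arrays[f"bn{i}_var"] = bn.running_var
        np.savez_compressed(path, **arrays)
        meta = {"config": {k: list(v) if isinstance(v, tuple) else v
                           for k, v in self.config.__dict__.items()},
                "seed": self.seed}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "RNFLNet":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        cfg = meta["config"]
        cfg["input_shape"] = tuple(cfg["input_shape"])
        model = cls(NetConfig(**cfg), seed=meta["seed"])
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        for i, p in enumerate(model.params()):
            p.value = data[f"p{i}"]
        bns = [l for l in model._all_layers() if isinstance(l, nn.BatchNorm)]
        for i, bn in enumerate(bns):
            bn.running_mean = data[f"bn{i}_mean"]
            bn.running_var = data[f"bn{i}_var"]
        return model


def build_rnflnet(config: NetConfig | None = None, seed: int = 0) -> RNFLNet:
    """Construct the network; identical seeds give identical weights."""
    return RNFLNet(config or NetConfig(), seed=seed)


def dice_loss(pred: np.ndarray, target: np.ndarray,
              eps: float = EPSILON) -> float:
    """Soft Dice loss: 1 - mean over classes of
    (2 sum(p t) + eps) / (sum(p) + sum(t) + eps), sums over all pixels
    (and the batch).  In [0, 1]; 0 for a perfect binary match."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    axes = tuple(i for i in range(pred.ndim) if i != 1) if pred.ndim == 4 else None
    if pred.ndim == 4:  # (N, K, H, W)
        s = (pred * target).sum(axis=axes)
        p = pred.sum(axis=axes)
        t = target.sum(axis=axes)
    else:  # (H, W, K) single sample, channel-last
        s = (pred * target).sum(axis=(0, 1))
        p = pred.sum(axis=(0, 1))
        t = target.sum(axis=(0, 1))
    per_class = (2.0 * s + eps) / (p + t + eps)
    return float(1.0 - per_class.mean())


def _dice_loss_grad(pred: np.ndarray, target: np.ndarray,
                    eps: float = EPSILON) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. the probabilities, NCHW batch form."""
    k = pred.shape[1]
    s = (pred * target).sum(axis=(0, 2, 3))
    p = pred.sum(axis=(0, 2, 3))
    t = target.sum(axis=(0, 2, 3))
    denom = p + t + eps
    per_class = (2.0 * s + eps) / denom
    loss = float(1.0 - per_class.mean())
    # d/dp of -(1/K) * (2S+eps)/(P+T+eps): quotient rule per class
    grad = -(2.0 * target * denom[None, :, None, None]
             - (2.0 * s + eps)[None, :, None, None]) / (
        k * denom[None, :, None, None] ** 2
    )
    return loss, grad.astype(pred.dtype)


@dataclass
class TrainState:
    """Per-epoch training record."""

    epochs_run: int = 0
    learning_rate: float = 0.0
    seed: int = 0
    history: dict = field(default_factory=lambda: {
        "train_loss": [], "val_loss": [], "val_dice": [], "lr": []
    })


def _to_nchw(dataset) -> tuple[np.ndarray, np.ndarray]:
    """(image HxW, one-hot HxWxK) pairs -> float32 NCHW batches."""
    images = np.stack([np.asarray(img) for img, _ in dataset])
    masks = np.stack([np.asarray(m) for _, m in dataset])
    x = images[:, None, :, :].astype(np.float32)
    y = np.ascontiguousarray(masks.transpose(0, 3, 1, 2)).astype(np.float32)
    return x, y


def train(
    model: RNFLNet,
    train_set,
    val_set,
    epochs: int | None = None,
    batch_size: int | None = None,
    seed: int = 0,
    target_train_dice: float | None = None,
    check_every: int = 5,
) -> tuple[RNFLNet, TrainState]:
    """Train with Adam (lr 1e-4) and a soft Dice loss.

    The learning rate halves when the validation loss fails to improve
    for ``lr_patience`` epochs and never drops below ``lr_floor``.  If
    ``target_train_dice`` is set, training stops once the evaluation-mode
    RNFL Dice on the training set reaches it (checked every
    ``check_every`` epochs) — useful for deliberate-overfit fitting on
    small synthetic sets.  Fully deterministic under ``seed``.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    batch_size = cfg.batch_size if batch_size is None else batch_size
    x_train, y_train = _to_nchw(train_set)
    x_val, y_val = _to_nchw(val_set)

    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.params(), lr=cfg.lr_initial)
    state = TrainState(seed=seed, learning_rate=cfg.lr_initial)
    best_val = np.inf
    since_best = 0

    for epoch in range(epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            probs = model.forward(x_train[idx], training=True)
            loss, grad = _dice_loss_grad(probs, y_train[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        if not np.isfinite(train_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")

        val_probs = model.forward(x_val, training=False)
        val_loss = dice_loss(val_probs, y_val)
        val_pred = probabilities_to_mask(
            np.ascontiguousarray(val_probs.transpose(0, 2, 3, 1))
        )
        val_gt = np.argmax(y_val, axis=1)
        val_dice = float(np.mean([
            dice_metric(val_pred[i], val_gt[i], RNFL) for i in range(len(val_pred))
        ]))

        state.history["train_loss"].append(train_loss)
        state.history["val_loss"].append(val_loss)
        state.history["val_dice"].append(val_dice)
        state.history["lr"].append(opt.lr)
        state.epochs_run = epoch + 1
        state.learning_rate = opt.lr

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.lr_patience:
                opt.lr = max(cfg.lr_floor, opt.lr * cfg.lr_decay_factor)
                since_best = 0

        if target_train_dice is not None and (epoch + 1) % check_every == 0:
            probs = model.forward(x_train, training=False)
            pred = probabilities_to_mask(
                np.ascontiguousarray(probs.transpose(0, 2, 3, 1))
            )
            gt = np.argmax(y_train, axis=1)
            train_dice = float(np.mean([
                dice_metric(pred[i], gt[i], RNFL) for i in range(len(pred))
            ]))
            if train_dice >= target_train_dice:
                break

    return model, state


def predict(model: RNFLNet, image: np.ndarray) -> np.ndarray:
    """Evaluation-mode forward pass on one normalized image.

    Returns the (H, W, n_classes) sigmoid probability map.  Dropout is
    off and batch normalization uses running statistics, so repeated
    calls are bit-identical.
    """
    image = np.asarray(image)
    h, w, _ = model.config.input_shape
    if image.shape != (h, w):
        raise ValueError(
            f"expected a ({h}, {w}) image, got {image.shape}"
        )
    x = image[None, None].astype(np.float32)
    probs = model.forward(x, training=False)
    return np.ascontiguousarray(probs[0].transpose(1, 2, 0)).astype(np.float64)


def probabilities_to_mask(probmap: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the channel-last class axis; ties go to the
    lowest class index.  Column monotonicity is *not* enforced — the
    boundary extractor in the metrics module handles ragged columns."""
    return np.argmax(probmap, axis=-1).astype(np.int64)
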