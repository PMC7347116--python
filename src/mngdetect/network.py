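"""U-Net heatmap network: a compact CPU implementation with explicit
forward/backward passes.

The architecture is the canonical encoder-decoder: a contracting path of
paired same-padded 3x3 convolutions + ReLU with 2x2 max pooling and filter
counts doubling per level, an expanding path of 2x2 transposed convolutions
with skip concatenations, and a final 1x1 convolution with a sigmoid head.
Training minimizes pixel-wise binary cross-entropy against filled MNG area
masks with Adam, one checkpoint per epoch, each epoch starting from the
previous epoch's weights. Model output p in [0, 1] is scaled to integer
brightness round(255 * p).

Depth and base filter count are configurable so the same code covers both the
canonical 512x512/depth-4/64-filter geometry and desk-scale runs
(128x128/depth-3/8-filter) that train in minutes on one CPU core.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .heatmap import HeatMap
from .panels import Panel, stitch, tile_for_inference
from .slides import SlideImage

__all__ = [
    "NetworkConfig",
    "EpochCheckpoint",
    "UNet",
    "build_network",
    "train",
    "predict_heatmap",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    input_size: int = 512
    depth: int = 4
    base_filters: int = 64
    epochs: int = 15
    batch_size: int = 4
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % (2**self.depth):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth"
            )
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or self.base_filters < 1 or self.depth < 1:
            raise ValueError("batch_size, base_filters, depth must be >= 1")


# ---------------------------------------------------------------------------
# layers (NHWC, float32)


class _Conv3x3:
    """Same-padded 3x3 convolution, computed as 9 shifted matmuls."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * cin))  # He init
        self.W = rng.normal(0, scale, (3, 3, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self._xp = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        b_, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        y = np.broadcast_to(self.b, (b_, h, w, self.b.size)).copy()
        for di in range(3):
            for dj in range(3):
                y += xp[:, di : di + h, dj : dj + w, :] @ self.W[di, dj]
        self._xp = xp if cache else None
        return y

    def backward(self, dy: np.ndarray):
        xp = self._xp
        b_, h, w, _ = dy.shape
        self.db = dy.sum(axis=(0, 1, 2))
        self.dW = np.empty_like(self.W)
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                xs = xp[:, di : di + h, dj : dj + w, :]
                self.dW[di, dj] = np.tensordot(xs, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di : di + h, dj : dj + w, :] += dy @ self.W[di, dj].T
        self._xp = None
        return dxp[:, 1:-1, 1:-1, :]

    def params(self):
        return [("W", self), ("b", self)]


class _Conv1x1:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.W = rng.normal(0, np.sqrt(2.0 / cin), (cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self._x = None

    def forward(self, x, cache):
        self._x = x if cache else None
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = np.tensordot(self._x, dy, axes=([0, 1, 2], [0, 1, 2]))
        self.db = dy.sum(axis=(0, 1, 2))
        dx = dy @ self.W.T
        self._x = None
        return dx


class _ReLU:
    def forward(self, x, cache):
        y = np.maximum(x, 0)
        self._mask = x > 0 if cache else None
        return y

    def backward(self, dy):
        dy = dy * self._mask
        self._mask = None
        return dy


class _MaxPool2:
    def forward(self, x, cache):
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        if cache:
            # route gradient to (all) maxima; exact ties are measure-zero
            self._mask = xr == y[:, :, None, :, None, :]
            self._shape = x.shape
        return y

    def backward(self, dy):
        b, h2, w2, c = dy.shape
        dxr = self._mask * dy[:, :, None, :, None, :]
        self._mask = None
        return dxr.reshape(self._shape)


class _UpConv2:
    """2x2 transposed convolution with stride 2 (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.W = rng.normal(0, scale, (2, 2, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self._x = None

    def forward(self, x, cache):
        b, h, w, cin = x.shape
        cout = self.b.size
        # y[b, 2i+di, 2j+dj, k] = sum_c x[b,i,j,c] W[di,dj,c,k] + b[k]
        y = np.einsum("bijc,uvck->biujvk", x, self.W, optimize=True)
        y = y.reshape(b, 2 * h, 2 * w, cout) + self.b
        self._x = x if cache else None
        return y

    def backward(self, dy):
        b, h2, w2, cout = dy.shape
        dyr = dy.reshape(b, h2 // 2, 2, w2 // 2, 2, cout)
        self.db = dy.sum(axis=(0, 1, 2))
        self.dW = np.einsum("bijc,biujvk->uvck", self._x, dyr, optimize=True)
        dx = np.einsum("biujvk,uvck->bijc", dyr, self.W, optimize=True)
        self._x = None
        return dx


# ---------------------------------------------------------------------------
# model


class UNet:
    """Encoder-decoder heatmap model. Input (B, S, S, 1) in [0, 1]; output
    per-pixel probability of MNG membership, same spatial shape."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        F, D = config.base_filters, config.depth
        self.enc: list[tuple] = []
        cin = 1
        for lvl in range(D):
            cout = F * 2**lvl
            self.enc.append(
                (_Conv3x3(cin, cout, rng), _ReLU(), _Conv3x3(cout, cout, rng), _ReLU())
            )
            cin = cout
        cb = F * 2**D
        self.bott = (_Conv3x3(cin, cb, rng), _ReLU(), _Conv3x3(cb, cb, rng), _ReLU())
        self.dec: list[tuple] = []
        cin = cb
        for lvl in reversed(range(D)):
            cskip = F * 2**lvl
            self.dec.append(
                (
                    _UpConv2(cin, cskip, rng),
                    _Conv3x3(2 * cskip, cskip, rng),
                    _ReLU(),
                    _Conv3x3(cskip, cskip, rng),
                    _ReLU(),
                )
            )
            cin = cskip
        self.head = _Conv1x1(cin, 1, rng)
        self.pools = [_MaxPool2() for _ in range(D)]

    # -- parameter plumbing -------------------------------------------------
    def _layers_with_params(self):
        for block in self.enc:
            yield block[0]
            yield block[2]
        yield self.bott[0]
        yield self.bott[2]
        for block in self.dec:
            yield block[0]
            yield block[1]
            yield block[3]
        yield self.head

    def get_params(self) -> list[np.ndarray]:
        out = []
        for lay in self._layers_with_params():
            out.extend([lay.W, lay.b])
        return out

    def set_params(self, params: Sequence[np.ndarray]) -> None:
        it = iter(params)
        for lay in self._layers_with_params():
            lay.W = next(it).astype(np.float32)
            lay.b = next(it).astype(np.float32)

    def get_grads(self) -> list[np.ndarray]:
        out = []
        for lay in self._layers_with_params():
            out.extend([lay.dW, lay.db])
        return out

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        skips = []
        for block, pool in zip(self.enc, self.pools):
            for lay in block:
                x = lay.forward(x, cache)
            skips.append(x)
            x = pool.forward(x, cache)
        for lay in self.bott:
            x = lay.forward(x, cache)
        self._concat_ch = []
        for block, skip in zip(self.dec, reversed(skips)):
            up = block[0].forward(x, cache)
            x = np.concatenate([skip, up], axis=-1)
            self._concat_ch.append(skip.shape[-1])
            for lay in block[1:]:
                x = lay.forward(x, cache)
        return self.head.forward(x, cache)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for block, csk in zip(reversed(self.dec), reversed(self._concat_ch)):
            for lay in reversed(block[1:]):
                dx = lay.backward(dx)
            dskips.append(dx[..., :csk])
            dx = block[0].backward(dx[..., csk:])
        for lay in reversed(self.bott):
            dx = lay.backward(dx)
        # dskips were collected shallow-first; encoder unwinds deep-first
        for block, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dx = pool.backward(dx) + dskip
            for lay in reversed(block):
                dx = lay.backward(dx)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid output in [0, 1] for a (B, S, S, 1) batch."""
        return _sigmoid(self.forward_logits(x, cache=False))


def build_network(config: NetworkConfig) -> UNet:
    """Construct a seeded U-Net; same config -> identical initial weights."""
    return UNet(config)


# ---------------------------------------------------------------------------
# training


@dataclass
class EpochCheckpoint:
    """Weights and training loss after one full pass over the panel set."""

    epoch_index: int
    params: list[np.ndarray]
    loss: float
    config: NetworkConfig = field(default_factory=NetworkConfig)

    @property
    def checkpoint_id(self) -> str:
        return f"epoch_{self.epoch_index:02d}"

    def build_model(self) -> UNet:
        model = UNet(self.config)
        model.set_params(self.params)
        return model


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable pixel-mean BCE; returns (loss, dloss/dz)."""
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    p = _sigmoid(z)
    return float(loss.mean()), ((p - t) / z.size).astype(np.float32)


def train(
    model: UNet, panels: Sequence[Panel], config: NetworkConfig | None = None
) -> list[EpochCheckpoint]:
    """Train for ``config.epochs`` full passes over the panels, Adam + BCE.

    Panel order is reshuffled each epoch (seeded); one checkpoint is saved per
    epoch, and epoch N starts from epoch N-1's weights.
    """
    if config is None:
        config = model.config
    if not panels:
        raise ValueError("cannot train on an empty panel list")
    s = config.input_size
    for pn in panels:
        if pn.image_patch.shape != (s, s):
            raise ValueError(
                f"panel shape {pn.image_patch.shape} != input size {s}"
            )

    x_all = np.stack([pn.image_patch for pn in panels]).astype(np.float32)
    x_all = x_all[..., None] / 255.0
    t_all = np.stack([pn.mask_patch for pn in panels]).astype(np.float32)[..., None]

    params = model.get_params()
    opt = _Adam(params, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    checkpoints: list[EpochCheckpoint] = []
    n = len(panels)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            z = model.forward_logits(x_all[idx], cache=True)
            loss, dz = _bce_with_logits(z, t_all[idx])
            model.backward(dz)
            opt.step(params, model.get_grads())
            losses.append(loss)
        checkpoints.append(
            EpochCheckpoint(
                epoch_index=epoch,
                params=[p.copy() for p in params],
                loss=float(np.mean(losses)),
                config=config,
            )
        )
    return checkpoints


# ---------------------------------------------------------------------------
# prediction


def predict_heatmap(
    checkpoint: EpochCheckpoint | UNet,
    image: SlideImage,
    panel_size: int | None = None,
    stride: int | None = None,
) -> HeatMap:
    """Predict a whole-image 0-255 heatmap: tile, run the model per tile,
    stitch with mean blending, scale p to round(255 * p)."""
    if isinstance(checkpoint, EpochCheckpoint):
        model = checkpoint.build_model()
        ckpt_id = checkpoint.checkpoint_id
    else:
        model, ckpt_id = checkpoint, "model"
    if panel_size is None:
        panel_size = model.config.input_size
    tiles = tile_for_inference(image, panel_size, stride)
    heat_tiles = []
    batch = max(1, model.config.batch_size)
    for start in range(0, len(tiles), batch):
        chunk = tiles[start : start + batch]
        x = np.stack([t[0] for t in chunk]).astype(np.float32)[..., None] / 255.0
        p = model.predict_proba(x)[..., 0]
        for (tile, xo, yo), prob in zip(chunk, p):
            heat_tiles.append((255.0 * prob, xo, yo))
    return stitch(
        heat_tiles,
        image.shape,
        source_image_id=f"{image.slide_id}/{image.slice_id}",
        checkpoint_id=ckpt_id,
    )


# ---------------------------------------------------------------------------
# checkpoint serialization


def save_checkpoint(checkpoint: EpochCheckpoint, path: str | Path) -> None:
    """Serialize weights + config to an .npz file."""
    cfg = checkpoint.config
    meta = np.array(
        [
            cfg.input_size,
            cfg.depth,
            cfg.base_filters,
            cfg.epochs,
            cfg.batch_size,
            cfg.seed,
            checkpoint.epoch_index,
        ],
        dtype=np.int64,
    )
    arrays = {f"p{i:03d}": p for i, p in enumerate(checkpoint.params)}
    np.savez(
        path,
        _meta=meta,
        _lr=np.float64(cfg.learning_rate),
        _loss=np.float64(checkpoint.loss),
        **arrays,
    )


def load_checkpoint(path: str | Path) -> EpochCheckpoint:
    with np.load(path) as data:
        meta = data["_meta"]
        cfg = NetworkConfig(
            input_size=int(meta[0]),
            depth=int(meta[1]),
            base_filters=int(meta[2]),
            epochs=int(meta[3]),
            batch_size=int(meta[4]),
            learning_rate=float(data["_lr"]),
            seed=int(meta[5]),
        )
        keys = sorted(k for k in data.files if k.startswith("p"))
        params = [data[k] for k in keys]
        return EpochCheckpoint(
            epoch_index=int(meta[6]),
            params=params,
            loss=float(data["_loss"]),
            config=cfg,
        )
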