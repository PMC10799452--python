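"""Pure-numpy 2D encoder-decoder network for flow-field regression.

A U-Net-style architecture: ``depth`` resolution levels with two 3x3
convolutions + ReLU per level, 2x2 max-pooling on the way down, nearest-
neighbour upsampling with skip concatenation on the way up, and a 1x1
head producing three output channels (two flow gradients and an ROI
logit).  Forward and backward passes are written directly in numpy
(im2col convolutions via ``sliding_window_view``), so training runs
anywhere numpy runs; model sizes here are small and images are 2D slices,
which keeps CPU training practical.

Optimization uses RAdam (rectified Adam) with the defaults
beta1 = 0.95, beta2 = 0.999, weight decay 1e-5, eps 1e-8, an initial
learning rate of 0.002 decayed by 0.1 at a configurable epoch, and batch
size 8.  The loss is ``flow_loss_weight`` x mean squared error on the two
gradient channels plus binary cross-entropy on the ROI channel.
Augmentation applies joint flips, 90-degree rotations and scalings to the
image and its targets, with the gradient components permuted and negated
consistently with the spatial transform.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage as ndi

__all__ = ["TrainConfig", "UNet", "RAdam", "build_network", "train",
           "flow_loss", "save_model", "load_model", "normalize_image"]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the full-scale schedule)."""

    epochs: int = 250
    beta1: float = 0.95
    beta2: float = 0.999
    weight_decay: float = 1e-5
    eps: float = 1e-8
    flow_loss_weight: float = 5.0
    initial_lr: float = 0.002
    lr_decay_factor: float = 0.1
    lr_decay_epoch: int = 200
    batch_size: int = 8
    warmup_epochs: int = 10
    base_feature_maps: int = 48
    depth: int = 4
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        for name in ("epochs", "batch_size", "base_feature_maps", "initial_lr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# layers


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padding 3x3 (or 1x1) convolution; returns (y, cached windows)."""
    k = w.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    y = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,Cout)
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2)) + b[None, :, None, None]
    return y, win


def _conv2d_backward(dy: np.ndarray, win: np.ndarray, w: np.ndarray):
    """Gradients of a same-padding convolution: (dx, dw, db)."""
    k = w.shape[2]
    pad = k // 2
    dw = np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3]))  # (Cout,C,k,k)
    db = dy.sum(axis=(0, 2, 3))
    wt = w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]  # (Cin,Cout,k,k)
    dyp = np.pad(dy, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    dwin = sliding_window_view(dyp, (k, k), axis=(2, 3))
    dx = np.tensordot(dwin, wt, axes=([1, 4, 5], [1, 2, 3]))
    return np.ascontiguousarray(dx.transpose(0, 3, 1, 2)), dw, db


def _maxpool2(x: np.ndarray):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = xr == y[:, :, :, None, :, None]
    # break ties toward the first maximum so the gradient is well-defined
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = (np.cumsum(flat, axis=-1) == 1) & flat
    first = first.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return y, np.ascontiguousarray(first)


def _maxpool2_back(dy: np.ndarray, mask: np.ndarray):
    n, c, hh, _, ww, _ = mask.shape
    return (mask * dy[:, :, :, None, :, None]).reshape(n, c, hh * 2, ww * 2)


def _upsample2(x: np.ndarray):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_back(dy: np.ndarray):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """Numpy U-Net with ``depth`` levels and ``nbase`` first-level features.

    Parameters live in ``self.params`` (name -> array); ``forward`` caches
    activations for ``backward``, which fills ``self.grads``.
    """

    def __init__(self, nbase: int = 48, depth: int = 4, in_channels: int = 1,
                 out_channels: int = 3, seed: int = 0):
        self.nbase, self.depth = nbase, depth
        self.in_channels, self.out_channels = in_channels, out_channels
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        feats = [nbase * 2**i for i in range(depth + 1)]
        cin = in_channels
        for i, f in enumerate(feats):  # encoder + bottleneck
            self._add_conv(rng, f"enc{i}a", cin, f)
            self._add_conv(rng, f"enc{i}b", f, f)
            cin = f
        for i in range(depth - 1, -1, -1):  # decoder
            f = feats[i]
            self._add_conv(rng, f"dec{i}a", feats[i + 1] + f, f)
            self._add_conv(rng, f"dec{i}b", f, f)
        w = rng.normal(0, np.sqrt(2.0 / feats[0]),
                       (out_channels, feats[0], 1, 1)).astype(np.float32)
        self.params["head_w"] = w
        self.params["head_b"] = np.zeros(out_channels, np.float32)
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def _add_conv(self, rng, name: str, cin: int, cout: int, k: int = 3):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.params[f"{name}_w"] = rng.normal(0, scale, (cout, cin, k, k)).astype(np.float32)
        self.params[f"{name}_b"] = np.zeros(cout, np.float32)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _conv_relu(self, name: str, x: np.ndarray, cache: dict):
        y, win = _conv2d(x, self.params[f"{name}_w"], self.params[f"{name}_b"])
        relu = y > 0
        cache[name] = (win, relu)
        return y * relu

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, C, H, W) -> (N, out_channels, H, W); H, W padded internally."""
        x = np.asarray(x, np.float32)
        n, c, h, w = x.shape
        m = 2**self.depth
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        cache: dict = {"pad": (h, w)}
        skips = []
        for i in range(self.depth):
            x = self._conv_relu(f"enc{i}a", x, cache)
            x = self._conv_relu(f"enc{i}b", x, cache)
            skips.append(x)
            x, pm = _maxpool2(x)
            cache[f"pool{i}"] = pm
        x = self._conv_relu(f"enc{self.depth}a", x, cache)
        x = self._conv_relu(f"enc{self.depth}b", x, cache)
        for i in range(self.depth - 1, -1, -1):
            x = _upsample2(x)
            x = np.concatenate([x, skips[i]], axis=1)
            cache[f"cat{i}"] = x.shape[1] - skips[i].shape[1]
            x = self._conv_relu(f"dec{i}a", x, cache)
            x = self._conv_relu(f"dec{i}b", x, cache)
        y, win = _conv2d(x, self.params["head_w"], self.params["head_b"])
        cache["head"] = win
        self._cache = cache
        return y[:, :, :h, :w]

    def backward(self, dy: np.ndarray) -> None:
        dy = np.asarray(dy, np.float32)
        cache = self._cache
        h, w = cache["pad"]
        full_h = dy.shape[2] + ((-h) % (2**self.depth))
        full_w = dy.shape[3] + ((-w) % (2**self.depth))
        if (full_h, full_w) != dy.shape[2:]:
            pad = np.zeros((*dy.shape[:2], full_h, full_w), dy.dtype)
            pad[:, :, :dy.shape[2], :dy.shape[3]] = dy
            dy = pad
        g = self.grads
        dx, dw, db = _conv2d_backward(dy, cache["head"], self.params["head_w"])
        g["head_w"], g["head_b"] = dw, db

        def back_conv(name, d):
            win, relu = cache[name]
            d = d * relu
            dx, dw, db = _conv2d_backward(d, win, self.params[f"{name}_w"])
            g[f"{name}_w"], g[f"{name}_b"] = dw, db
            return dx

        dskips = {}
        for i in range(0, self.depth):
            dx = back_conv(f"dec{i}b", dx)
            dx = back_conv(f"dec{i}a", dx)
            nup = cache[f"cat{i}"]
            dskips[i] = dx[:, nup:]
            dx = _upsample2_back(dx[:, :nup])
        dx = back_conv(f"enc{self.depth}b", dx)
        dx = back_conv(f"enc{self.depth}a", dx)
        for i in range(self.depth - 1, -1, -1):
            dx = _maxpool2_back(dx, cache[f"pool{i}"])
            dx = dx + dskips[i]
            dx = back_conv(f"enc{i}b", dx)
            dx = back_conv(f"enc{i}a", dx)


def build_network(config: TrainConfig, in_channels: int = 1) -> UNet:
    """U-Net per the config's base feature maps, depth and seed."""
    return UNet(nbase=config.base_feature_maps, depth=config.depth,
                in_channels=in_channels, out_channels=3, seed=config.seed)


# ---------------------------------------------------------------------------
# optimizer


class RAdam:
    """Rectified Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.002,
                 beta1: float = 0.95, beta2: float = 0.999,
                 weight_decay: float = 1e-5, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.wd, self.eps = weight_decay, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t, b2t = self.b1**self.t, self.b2**self.t
        rho = self.rho_inf - 2.0 * self.t * b2t / (1.0 - b2t)
        for k, p in self.params.items():
            grad = grads[k] + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grad**2
            m_hat = self.m[k] / (1 - b1t)
            if rho > 4.0:
                v_hat = np.sqrt(self.v[k] / (1 - b2t))
                rect = np.sqrt(((rho - 4) * (rho - 2) * self.rho_inf)
                               / ((self.rho_inf - 4) * (self.rho_inf - 2) * rho))
                p -= self.lr * rect * m_hat / (v_hat + self.eps)
            else:
                p -= self.lr * m_hat


# ---------------------------------------------------------------------------
# loss


def flow_loss(pred: np.ndarray, target: np.ndarray, flow_weight: float = 5.0):
    """Combined loss and its gradient.

    ``flow_weight`` x MSE over the two gradient channels plus binary
    cross-entropy (with logits) over the ROI channel.  Returns
    (loss, dloss/dpred).
    """
    n_flow = pred[:, :2].size
    n_roi = pred[:, 2].size
    diff = pred[:, :2] - target[:, :2]
    l2 = float((diff**2).sum() / n_flow)
    z = pred[:, 2]
    t = target[:, 2]
    bce = float(np.sum(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))) / n_roi)
    loss = flow_weight * l2 + bce
    dpred = np.zeros_like(pred)
    dpred[:, :2] = flow_weight * 2.0 * diff / n_flow
    dpred[:, 2] = (1.0 / (1.0 + np.exp(-z)) - t) / n_roi
    return loss, dpred


# ---------------------------------------------------------------------------
# augmentation


def _transform_pair(img: np.ndarray, target: np.ndarray, rng: np.random.Generator):
    """Joint random flip / rot90 / scale of an image and its flow target."""
    gy, gx, roi = target[0], target[1], target[2]
    k = int(rng.integers(4))
    if k:
        img = np.rot90(img, k)
        gy, gx, roi = (np.rot90(a, k) for a in (gy, gx, roi))
        for _ in range(k):  # each CCW quarter turn maps (gy,gx) -> (-gx,gy)
            gy, gx = -gx, gy
    if rng.random() < 0.5:
        img = img[::-1]
        gy, gx, roi = gy[::-1], gx[::-1], roi[::-1]
        gy = -gy
    if rng.random() < 0.5:
        img = img[:, ::-1]
        gy, gx, roi = gy[:, ::-1], gx[:, ::-1], roi[:, ::-1]
        gx = -gx
    s = float(rng.uniform(0.85, 1.15))
    if abs(s - 1.0) > 1e-3:
        h, w = img.shape
        def rescale(a, order=1):
            z = ndi.zoom(a, s, order=order)
            zh, zw = z.shape
            if zh >= h:
                top, left = (zh - h) // 2, (zw - w) // 2
                return z[top:top + h, left:left + w]
            out = np.zeros((h, w), a.dtype)
            top, left = (h - zh) // 2, (w - zw) // 2
            out[top:top + zh, left:left + zw] = z
            return out
        img = rescale(img)
        gy, gx = rescale(gy), rescale(gx)
        roi = (rescale(roi) > 0.5).astype(roi.dtype)
    return np.ascontiguousarray(img), np.ascontiguousarray(np.stack([gy, gx, roi]))


def normalize_image(img: np.ndarray) -> np.ndarray:
    """Percentile (1-99) intensity normalization of one slice."""
    lo, hi = np.percentile(img, [1, 99])
    if hi <= lo:
        return np.zeros_like(img, np.float32)
    return ((img - lo) / (hi - lo)).astype(np.float32)


# ---------------------------------------------------------------------------
# training loop


def train(
    model: UNet,
    train_pairs,
    config: TrainConfig,
    val_pairs=None,
) -> pd.DataFrame:
    """Train a flow network on (image, flow-target) pairs.

    ``train_pairs``/``val_pairs`` are sequences of ``(img2d, target3hw)``
    with raw grayscale images (normalized internally) and targets from
    :func:`pomecell.flow.targets.labels_to_flows`.  Returns the per-epoch
    loss log as a DataFrame with columns epoch, lr, train_loss, val_loss.
    The logged training loss is the mean pre-update batch loss.
    """
    if len(train_pairs) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = RAdam({k: v for k, v in model.params.items()}, lr=config.initial_lr,
                beta1=config.beta1, beta2=config.beta2,
                weight_decay=config.weight_decay, eps=config.eps)
    images = [normalize_image(np.asarray(im, np.float32)) for im, _ in train_pairs]
    targets = [np.asarray(t, np.float32) for _, t in train_pairs]
    val = None
    if val_pairs:
        val = ([normalize_image(np.asarray(im, np.float32)) for im, _ in val_pairs],
               [np.asarray(t, np.float32) for _, t in val_pairs])
    rows = []
    warmup = min(config.warmup_epochs, max(config.epochs // 4, 1))
    for epoch in range(config.epochs):
        # linear warmup guards against early ReLU die-off at fresh inits
        if epoch < warmup:
            opt.lr = config.initial_lr * (epoch + 1) / warmup
        elif epoch >= config.lr_decay_epoch:
            opt.lr = config.initial_lr * config.lr_decay_factor
        else:
            opt.lr = config.initial_lr
        order = rng.permutation(len(images))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if config.augment:
                pairs = [_transform_pair(images[i], targets[i], rng) for i in idx]
            else:
                pairs = [(images[i], targets[i]) for i in idx]
            x = np.stack([p[0] for p in pairs])[:, None]
            t = np.stack([p[1] for p in pairs])
            pred = model.forward(x)
            loss, dpred = flow_loss(pred, t, config.flow_loss_weight)
            model.backward(dpred)
            opt.step(model.grads)
            losses.append(loss)
        val_loss = np.nan
        if val is not None:
            vl = []
            for im, t in zip(*val):
                pred = model.forward(im[None, None])
                vl.append(flow_loss(pred, t[None], config.flow_loss_weight)[0])
            val_loss = float(np.mean(vl))
        rows.append({"epoch": epoch, "lr": opt.lr,
                     "train_loss": float(np.mean(losses)), "val_loss": val_loss})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence and prediction adapter


def save_model(model: UNet, config: TrainConfig, path) -> None:
    """Checkpoint: parameter arrays (.npz) plus a JSON config sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path / "weights.npz", **model.params)
    meta = {"config": asdict(config),
            "arch": {"nbase": model.nbase, "depth": model.depth,
                     "in_channels": model.in_channels,
                     "out_channels": model.out_channels}}
    (path / "config.json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> tuple[UNet, TrainConfig]:
    path = Path(path)
    meta = json.loads((path / "config.json").read_text())
    model = UNet(**meta["arch"])
    with np.load(path / "weights.npz") as data:
        for k in model.params:
            model.params[k] = data[k]
    return model, TrainConfig(**meta["config"])


class FlowPredictor:
    """Adapter giving a trained UNet the slice-predictor interface.

    Callable as ``f(img2d, orientation, index)`` for
    :func:`pomecell.flow.predict.predict_volume`; normalizes the slice,
    runs the network and applies the sigmoid to the ROI logit.
    """

    def __init__(self, model: UNet):
        self.model = model

    def __call__(self, img2d, orientation=None, index=None):
        x = normalize_image(np.asarray(img2d, np.float32))[None, None]
        pred = self.model.forward(x)[0]
        out = pred.copy()
        out[2] = 1.0 / (1.0 + np.exp(-pred[2]))
        return out
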