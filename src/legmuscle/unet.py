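"""Desk-scale 2D U-Net for slice-wise multiclass muscle segmentation.

A compact, self-contained numpy implementation of the classic
encoder-decoder segmentation network: residual convolution blocks with
instance normalization and LeakyReLU, stride-2 downsampling, nearest-
neighbour upsampling with skip concatenation, a combined soft-Dice +
cross-entropy loss and an AdamW optimizer. Everything (weight init, slice
sampling) runs off one seed, so training is bit-reproducible on CPU.

The default configuration mirrors a full-scale clinical setup (416x240
window; channels 64..1024; 150k iterations would be expressible), but the
intended use here is the tiny configuration — a few thousand iterations at
reduced width on synthetic phantoms — which trains in minutes on one CPU.
Training consumes the water image only by default, since muscle boundaries
are water-signal structures; a two-channel fat+water mode is available.

Implementation notes: convolutions use im2col (patch extraction +
matmul) with explicit col2im scatter in the backward pass; all math is
float32; batch size is 1 (one 2D window per step), so tensors are plain
(C, H, W) arrays.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core_io import FatWaterVolume, LabelMap, MUSCLE_LABELS


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    window: tuple[int, int] = (416, 240)
    channels: tuple[int, ...] = (64, 128, 256, 512, 1024)
    strides: tuple[int, ...] = (2, 2, 2, 2)
    num_res_units: int = 2
    leaky_slope: float = 0.01
    learning_rate: float = 1e-4
    lr_schedule: str = "constant"      # "constant" | "cosine" (decay to 1% of lr)
    weight_decay: float = 1e-5
    batch_size: int = 1
    iterations: int = 1000
    n_classes: int = 11          # background + 10 muscle groups
    in_channels: int = 1         # water only; 2 = fat + water
    foreground_slice_prob: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if len(self.strides) != len(self.channels) - 1:
            raise ValueError("need len(strides) == len(channels) - 1")
        prod = math.prod(self.strides)
        if self.window[0] % prod or self.window[1] % prod:
            raise ValueError(
                f"window {self.window} must be divisible by the stride product {prod}")
        if self.iterations <= 0:
            raise ValueError("iterations must be > 0")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")

    @classmethod
    def tiny(cls, **overrides) -> "TrainConfig":
        """Reduced configuration that trains on a laptop CPU in minutes.

        Narrow channels but full depth — the deepest level's receptive
        field must span a leg so low-contrast sector boundaries can use
        angular context — with a higher, cosine-decayed learning rate
        (the full-scale 1e-4 is needlessly slow at this width).
        """
        kw = dict(window=(96, 64), channels=(12, 24, 48, 96),
                  strides=(2, 2, 2), iterations=2000,
                  learning_rate=1e-3, lr_schedule="cosine")
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# layers (single-sample CHW tensors, manual backward)
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Conv2d:
    def __init__(self, in_ch, out_ch, k, stride, rng):
        fan_in = in_ch * k * k
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), (out_ch, in_ch, k, k))
        self.w = Param(w)
        self.b = Param(np.zeros(out_ch))
        self.k, self.stride, self.pad = k, stride, k // 2
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s][:, :ho, :wo]              # (C, Ho, Wo, k, k)
        cols = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, c * k * k)
        w2 = self.w.value.reshape(self.w.value.shape[0], -1)
        out = cols @ w2.T + self.b.value
        self._cache = (cols, x.shape, ho, wo)
        return np.ascontiguousarray(out.reshape(ho, wo, -1).transpose(2, 0, 1))

    def backward(self, gy):
        cols, xshape, ho, wo = self._cache
        c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        o = gy.shape[0]
        gy2 = gy.transpose(1, 2, 0).reshape(ho * wo, o)
        self.w.grad += (gy2.T @ cols).reshape(self.w.value.shape)
        self.b.grad += gy2.sum(axis=0)
        gcols = (gy2 @ self.w.value.reshape(o, -1)).reshape(ho, wo, c, k, k)
        dxp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    gcols[:, :, :, ki, kj].transpose(2, 0, 1)
        return dxp[:, p:p + h, p:p + w]


class InstanceNorm:
    EPS = 1e-5

    def __init__(self, ch):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.EPS)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, gy):
        xhat, inv = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(1, 2))
        self.beta.grad += gy.sum(axis=(1, 2))
        g = gy * self.gamma.value[:, None, None]
        m1 = g.mean(axis=(1, 2), keepdims=True)
        m2 = (g * xhat).mean(axis=(1, 2), keepdims=True)
        return inv * (g - m1 - xhat * m2)


class LeakyReLU:
    def __init__(self, slope):
        self.slope = slope
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy)


class ResBlock:
    """conv(stride)-norm-act-conv-norm with a (projected) residual skip."""

    def __init__(self, in_ch, out_ch, stride, slope, rng, n_convs=2):
        self.layers = []
        ch = in_ch
        for i in range(n_convs):
            s = stride if i == 0 else 1
            self.layers.append(Conv2d(ch, out_ch, 3, s, rng))
            self.layers.append(InstanceNorm(out_ch))
            if i < n_convs - 1:
                self.layers.append(LeakyReLU(slope))
            ch = out_ch
        self.skip = (Conv2d(in_ch, out_ch, 1, stride, rng)
                     if (in_ch != out_ch or stride != 1) else None)
        self.act = LeakyReLU(slope)

    def params(self):
        ps = [p for l in self.layers for p in l.params()]
        if self.skip is not None:
            ps += self.skip.params()
        return ps

    def forward(self, x):
        h = x
        for l in self.layers:
            h = l.forward(h)
        r = self.skip.forward(x) if self.skip is not None else x
        return self.act.forward(h + r)

    def backward(self, gy):
        g = self.act.backward(gy)
        gr = self.skip.backward(g) if self.skip is not None else g
        gh = g
        for l in reversed(self.layers):
            gh = l.backward(gh)
        return gh + gr


def _upsample(x, s):
    return np.repeat(np.repeat(x, s, axis=1), s, axis=2)


def _upsample_back(gy, s):
    c, h, w = gy.shape
    return gy.reshape(c, h // s, s, w // s, s).sum(axis=(2, 4))


class UNet2D:
    """Encoder-decoder with skip concatenation; depth from the channel list."""

    def __init__(self, cfg: TrainConfig, rng):
        ch = cfg.channels
        self.cfg = cfg
        self.enc = [ResBlock(cfg.in_channels, ch[0], 1, cfg.leaky_slope, rng,
                             cfg.num_res_units)]
        for i in range(1, len(ch)):
            self.enc.append(ResBlock(ch[i - 1], ch[i], cfg.strides[i - 1],
                                     cfg.leaky_slope, rng, cfg.num_res_units))
        self.dec = []
        for i in range(len(ch) - 2, -1, -1):
            self.dec.append(ResBlock(ch[i + 1] + ch[i], ch[i], 1,
                                     cfg.leaky_slope, rng, cfg.num_res_units))
        self.head = Conv2d(ch[0], cfg.n_classes, 1, 1, rng)
        self._cache = None

    def params(self):
        ps = [p for b in self.enc + self.dec for p in b.params()]
        return ps + self.head.params()

    def forward(self, x):
        skips = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk.forward(h)
            if i < len(self.enc) - 1:
                skips.append(h)
        concat_ch = []
        for j, blk in enumerate(self.dec):
            lvl = len(self.enc) - 2 - j
            h = _upsample(h, self.cfg.strides[lvl])
            skip = skips[lvl]
            concat_ch.append(h.shape[0])
            h = np.concatenate([h, skip], axis=0)
            h = blk.forward(h)
        self._cache = concat_ch
        return self.head.forward(h)

    def backward(self, glogits):
        """Backpropagate through decoder, skips and encoder; returns dL/dx."""
        concat_ch = self._cache
        g = self.head.backward(glogits)
        gskips = {}
        for j in range(len(self.dec) - 1, -1, -1):
            lvl = len(self.enc) - 2 - j
            g = self.dec[j].backward(g)
            cu = concat_ch[j]
            gup, gskip = g[:cu], g[cu:]
            gskips[lvl] = gskips.get(lvl, 0) + gskip
            g = _upsample_back(gup, self.cfg.strides[lvl])
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.enc) - 1:
                g = g + gskips.get(i, 0)
            g = self.enc[i].backward(g)
        return g


def softmax(z):
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def dice_ce_loss(logits: np.ndarray, target: np.ndarray,
                 smooth: float = 1e-5) -> tuple[float, np.ndarray]:
    """Combined soft-Dice + cross-entropy loss and its gradient w.r.t. logits.

    ``logits`` is (K, H, W); ``target`` is an integer (H, W) class map.
    Dice averages over all K classes with additive smoothing so empty
    classes are well-defined.
    """
    k, h, w = logits.shape
    npix = h * w
    p = softmax(logits.astype(np.float64))
    onehot = np.zeros_like(p)
    idx = target.reshape(-1)
    onehot.reshape(k, -1)[idx, np.arange(npix)] = 1.0

    ce = float(-np.log(np.maximum(p.reshape(k, -1)[idx, np.arange(npix)],
                                  1e-12)).mean())
    g_ce = (p - onehot) / npix

    inter = (p * onehot).sum(axis=(1, 2))
    union = p.sum(axis=(1, 2)) + onehot.sum(axis=(1, 2))
    dice_k = (2.0 * inter + smooth) / (union + smooth)
    dice_loss = float(1.0 - dice_k.mean())
    # d(dice_k)/dp_k = (2*t*(U+s) - (2I+s)) / (U+s)^2 ; loss = 1 - mean_k dice_k
    gp = -(2.0 * onehot * (union + smooth)[:, None, None]
           - (2.0 * inter + smooth)[:, None, None]) / \
        ((union + smooth) ** 2)[:, None, None] / k
    # chain through softmax: dL/dz = p * (gp - sum_k gp*p)
    g_dice = p * (gp - (gp * p).sum(axis=0, keepdims=True))

    grad = (g_ce + g_dice).astype(np.float32)
    return ce + dice_loss, grad


class AdamW:
    def __init__(self, params, lr, weight_decay, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, b1, b2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p in self.params:
            p.m[...] = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v[...] = self.b2 * p.v + (1 - self.b2) * p.grad ** 2
            p.value[...] -= self.lr * (p.m / b1t / (np.sqrt(p.v / b2t) + self.eps)
                                       + self.wd * p.value)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _pad_crop(arr2d: np.ndarray, window: tuple[int, int], cval=0.0):
    """Center pad-or-crop a 2D array to the window; returns array + the
    slices needed to undo it."""
    h, w = arr2d.shape
    wh, ww = window
    out = np.full((wh, ww), cval, dtype=arr2d.dtype)
    h0 = max((wh - h) // 2, 0)
    w0 = max((ww - w) // 2, 0)
    sh0 = max((h - wh) // 2, 0)
    sw0 = max((w - ww) // 2, 0)
    ch = min(h, wh)
    cw = min(w, ww)
    out[h0:h0 + ch, w0:w0 + cw] = arr2d[sh0:sh0 + ch, sw0:sw0 + cw]
    return out, (h0, w0, sh0, sw0, ch, cw)


def _input_slices(vol: FatWaterVolume, cfg: TrainConfig) -> np.ndarray:
    """Normalized network input, shape (in_channels, H, W, Z)."""
    scale = max(float((vol.fat + vol.water).max()), 1e-8)
    chans = [vol.water / scale]
    if cfg.in_channels == 2:
        chans.insert(0, vol.fat / scale)
    elif cfg.in_channels != 1:
        raise ValueError("in_channels must be 1 (water) or 2 (fat+water)")
    return np.stack(chans, axis=0).astype(np.float32)


@dataclass
class UNetModel:
    """Trained model handle: network, config and the label table it predicts."""

    net: UNet2D
    cfg: TrainConfig
    label_table: dict = field(default_factory=lambda: dict(MUSCLE_LABELS))

    def predict_slice(self, x2d: np.ndarray) -> np.ndarray:
        win, undo = _pad_crop_multi(x2d, self.cfg.window)
        logits = self.net.forward(win)
        pred = logits.argmax(axis=0).astype(np.int16)
        h0, w0, sh0, sw0, ch, cw = undo
        out = np.zeros(x2d.shape[1:], dtype=np.int16)
        out[sh0:sh0 + ch, sw0:sw0 + cw] = pred[h0:h0 + ch, w0:w0 + cw]
        return out

    def save(self, path):
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        vals = {f"p{i}": p.value for i, p in enumerate(self.net.params())}
        np.savez(path / "weights.npz", **vals)
        meta = {"config": asdict(self.cfg),
                "label_table": {str(k): list(v) for k, v in self.label_table.items()}}
        (path / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "UNetModel":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        c = meta["config"]
        for key in ("window", "channels", "strides"):
            c[key] = tuple(c[key])
        cfg = TrainConfig(**c)
        net = UNet2D(cfg, np.random.default_rng(0))
        with np.load(path / "weights.npz") as z:
            for i, p in enumerate(net.params()):
                p.value[...] = z[f"p{i}"]
        table = {int(k): tuple(v) for k, v in meta["label_table"].items()}
        return cls(net=net, cfg=cfg, label_table=table)


def _pad_crop_multi(x: np.ndarray, window):
    outs, undo = [], None
    for c in range(x.shape[0]):
        o, undo = _pad_crop(x[c], window)
        outs.append(o)
    return np.stack(outs, axis=0), undo


def train_2d_unet(volumes: list[FatWaterVolume], labels: list[LabelMap],
                  cfg: TrainConfig) -> tuple[UNetModel, np.ndarray]:
    """Train the network on axial slices of the given volumes.

    Slices containing foreground are sampled with probability
    ``cfg.foreground_slice_prob``, any slice otherwise (at batch size 1 a
    foreground bias is needed or background slices dominate). Returns the
    model handle and the per-iteration loss trace. Fully deterministic for
    a fixed config and seed.
    """
    if not volumes or len(volumes) != len(labels):
        raise ValueError("need equally many volumes and label maps (>= 1)")
    for v, l in zip(volumes, labels):
        v.geometry.require_match(l.geometry, what="training image and labels")
        if int(l.labels.max(initial=0)) >= cfg.n_classes:
            raise ValueError(
                f"label {int(l.labels.max())} exceeds n_classes={cfg.n_classes}")
        if v.shape[0] > cfg.window[0] or v.shape[1] > cfg.window[1]:
            raise ValueError(
                f"slice {v.shape[:2]} larger than window {cfg.window}; "
                f"enlarge the window")

    rng = np.random.default_rng(cfg.seed)
    net = UNet2D(cfg, rng)
    opt = AdamW(net.params(), cfg.learning_rate, cfg.weight_decay)

    inputs = [_input_slices(v, cfg) for v in volumes]
    fg, bg = [], []
    for vi, lm in enumerate(labels):
        for z in range(lm.labels.shape[2]):
            (fg if lm.labels[:, :, z].any() else bg).append((vi, z))
    if not fg:
        fg = bg

    losses = np.empty(cfg.iterations, dtype=np.float64)
    for it in range(cfg.iterations):
        if cfg.lr_schedule == "cosine":
            frac = it / max(cfg.iterations - 1, 1)
            opt.lr = cfg.learning_rate * (0.01 + 0.99 * 0.5 *
                                          (1 + math.cos(math.pi * frac)))
        pool = fg if (not bg or rng.random() < cfg.foreground_slice_prob) else bg
        vi, z = pool[rng.integers(len(pool))]
        x, undo = _pad_crop_multi(inputs[vi][:, :, :, z], cfg.window)
        y, _ = _pad_crop(labels[vi].labels[:, :, z].astype(np.int64),
                         cfg.window, cval=0)
        logits = net.forward(x)
        loss, glog = dice_ce_loss(logits, y)
        opt.zero_grad()
        net.backward(glog)
        opt.step()
        losses[it] = loss
    return UNetModel(net=net, cfg=cfg), losses


def infer_volume(model: UNetModel, vol: FatWaterVolume) -> LabelMap:
    """Slice-wise argmax prediction restitched into a 3D label map."""
    if vol.shape[0] > model.cfg.window[0] or vol.shape[1] > model.cfg.window[1]:
        raise ValueError(
            f"volume slices {vol.shape[:2]} exceed the model window "
            f"{model.cfg.window}")
    x = _input_slices(vol, model.cfg)
    out = np.zeros(vol.shape, dtype=np.int16)
    for z in range(vol.shape[2]):
        out[:, :, z] = model.predict_slice(x[:, :, :, z])
    return LabelMap(labels=out, geometry=vol.geometry,
                    label_table=model.label_table)
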