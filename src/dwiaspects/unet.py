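"""A 3-D U-Net lesion segmenter, implemented in NumPy.

The architecture follows the standard volumetric U-Net design: 3x3x3
convolutions for feature extraction, 2x2x2 max pooling in the encoder,
batch normalisation, transposed-convolution (or nearest-neighbour
interpolation) upsampling in the decoder, and skip connections fusing
features across scales. Training uses Adam with an initial learning rate
of 1e-2, 100 epochs and batch size 32 by default, and a soft-Dice loss
(cross-entropy + Dice available), with per-volume z-score intensity
normalisation.

Forward and backward passes are written directly against BLAS-backed
matrix multiplies (one GEMM per kernel offset with shifted-view
accumulation), so the module needs no deep learning framework and runs
at desk scale (e.g. 32^3 grids) on one CPU.
The segmenter is optional plumbing: the scoring pipeline accepts any
externally produced mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .volume_io import LabeledVolume


class UNetError(ValueError):
    pass


@dataclass
class UNetConfig:
    depth: int = 3                       # pooling stages
    convs_per_block: int = 2             # 2-4 convolutions per resolution block
    base_channels: int = 16
    norm: str = "batch"
    upsample: str = "transposed"         # 'transposed' | 'interpolation'
    learning_rate: float = 1e-2
    epochs: int = 100
    batch_size: int = 32
    loss: str = "dice"                   # 'dice' | 'ce+dice'
    head_bias_init: float = -2.0         # start near p~0.12: low-prevalence init
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.convs_per_block <= 4):
            raise UNetError("convs_per_block must lie in [2, 4]")
        if self.depth < 1:
            raise UNetError("depth must be >= 1")
        if self.upsample not in ("transposed", "interpolation"):
            raise UNetError(f"unknown upsample mode {self.upsample!r}")
        if self.loss not in ("dice", "ce+dice"):
            raise UNetError(f"unknown loss {self.loss!r}")


# ---------------------------------------------------------------------------
# layers
#
# Internally all activations are channels-LAST (N, D, H, W, C): convolutions
# then run as one GEMM over the whole padded array per kernel offset plus a
# shifted-view accumulation, which is markedly faster on one CPU than an
# im2col gather. Forward caches what backward needs; float32 throughout.

class _Layer:
    params: list[str] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _shift_conv(xp: np.ndarray, w: np.ndarray, out_shape) -> np.ndarray:
    """Valid 3^3 convolution of a padded (N,D+2,H+2,W+2,Ci) array.

    ``w`` is (3,3,3,Ci,Co). One GEMM per kernel offset over the full padded
    array, accumulated into shifted output views.
    """
    n, dp, hp, wp, ci = xp.shape
    d, h, ww_ = out_shape[1:4]
    co = w.shape[4]
    flat = xp.reshape(-1, ci)
    out = np.zeros((n, d, h, ww_, co), dtype=np.result_type(xp.dtype, w.dtype))
    for a in range(3):
        for b in range(3):
            for c in range(3):
                t = (flat @ w[a, b, c]).reshape(n, dp, hp, wp, co)
                out += t[:, a:a + d, b:b + h, c:c + ww_]
    return out


class _Conv3(_Layer):
    """3x3x3 same-padding convolution; weights (3,3,3,Ci,Co)."""

    params = ["w", "b"]

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 27))
        self.w = (rng.standard_normal((3, 3, 3, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        self.xp = xp if train else None
        return _shift_conv(xp, self.w, x.shape) + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, d, h, w_, co = grad.shape
        ci = self.w.shape[3]
        self.gb += grad.sum(axis=(0, 1, 2, 3))
        gflat = grad.reshape(-1, co)
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    patch = np.ascontiguousarray(
                        self.xp[:, a:a + d, b:b + h, c:c + w_]).reshape(-1, ci)
                    self.gw[a, b, c] += patch.T @ gflat
        # dX: full correlation = valid conv of the 1-padded grad with the
        # spatially flipped, channel-transposed kernels
        gp = np.pad(grad, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        wt = np.ascontiguousarray(
            self.w[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3))
        return _shift_conv(gp, wt, (n, d, h, w_, ci))


class _Conv1(_Layer):
    """1x1x1 convolution (the output head); weights (Ci, Co)."""

    params = ["w", "b"]

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.x = x if train else None
        return (x.reshape(-1, self.w.shape[0]) @ self.w).reshape(
            x.shape[:4] + (self.w.shape[1],)) + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        ci, co = self.w.shape
        g = grad.reshape(-1, co)
        self.gw += self.x.reshape(-1, ci).T @ g
        self.gb += g.sum(axis=0)
        return (g @ self.w.T).reshape(self.x.shape)


class _BatchNorm(_Layer):
    params = ["gamma", "beta"]

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 1, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self.istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * self.istd
        self.xhat = xhat if train else None
        return self.gamma * xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = (0, 1, 2, 3)
        m = int(np.prod(grad.shape[:4]))
        self.ggamma += (grad * self.xhat).sum(axis=axes)
        self.gbeta += grad.sum(axis=axes)
        dxhat = grad * self.gamma
        t1 = dxhat.sum(axis=axes)
        t2 = (dxhat * self.xhat).sum(axis=axes)
        return (dxhat - t1 / m - self.xhat * t2 / m) * self.istd


class _ReLU(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self.mask


class _MaxPool2(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, d, h, w, c = x.shape
        xr = x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4, 6))
        if train:
            winners = xr == y[:, :, None, :, None, :, None]
            counts = winners.sum(axis=(2, 4, 6), keepdims=True)
            self.scatter = winners / counts  # split grad among tied maxima
            self.in_shape = x.shape
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad[:, :, None, :, None, :, None] * self.scatter
        return g.reshape(self.in_shape)


class _ConvTranspose2(_Layer):
    """2x2x2 stride-2 transposed convolution; weights (Ci,Co,2,2,2)."""

    params = ["w", "b"]

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_in, c_out, 2, 2, 2)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.x = x if train else None
        n, d, h, w, ci = x.shape
        co = self.w.shape[1]
        y = np.einsum("ndhwi,ioabc->ndahbwco", x, self.w, optimize=True)
        y = np.ascontiguousarray(y).reshape(n, 2 * d, 2 * h, 2 * w, co)
        return y + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, d2, h2, w2, co = grad.shape
        g = grad.reshape(n, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2, co)
        self.gw += np.einsum("ndhwi,ndahbwco->ioabc", self.x, g, optimize=True)
        self.gb += grad.sum(axis=(0, 1, 2, 3))
        return np.einsum("ndahbwco,ioabc->ndhwi", g, self.w, optimize=True)


class _Upsample2(_Layer):
    """Parameter-free nearest-neighbour 2x upsampling (adjoint: block sum)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, d2, h2, w2, c = grad.shape
        return grad.reshape(n, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4, 6))


def _block(c_in: int, c_out: int, m: int, rng) -> list[_Layer]:
    layers: list[_Layer] = []
    for i in range(m):
        layers += [_Conv3(c_in if i == 0 else c_out, c_out, rng),
                   _BatchNorm(c_out), _ReLU()]
    return layers


# ---------------------------------------------------------------------------
# model

class UNet3D:
    """U-Net encoder-decoder with skip connections (see module docstring)."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        m = config.convs_per_block
        self.enc_blocks: list[list[_Layer]] = []
        self.pools: list[_MaxPool2] = []
        ch = 1
        enc_ch = []
        for i in range(config.depth):
            out = c * 2 ** i
            self.enc_blocks.append(_block(ch, out, m, rng))
            self.pools.append(_MaxPool2())
            enc_ch.append(out)
            ch = out
        self.bottleneck = _block(ch, c * 2 ** config.depth, m, rng)
        ch = c * 2 ** config.depth
        self.ups: list[_Layer] = []
        self.dec_blocks: list[list[_Layer]] = []
        for i in reversed(range(config.depth)):
            skip = enc_ch[i]
            if config.upsample == "transposed":
                self.ups.append(_ConvTranspose2(ch, skip, rng))
                up_out = skip
            else:
                self.ups.append(_Upsample2())
                up_out = ch
            self.dec_blocks.append(_block(up_out + skip, skip, m, rng))
            ch = skip
        self.head = _Conv1(ch, 1, rng)
        # foreground is rare: biasing the head toward "background" keeps the
        # initial soft-Dice denominator small and its gradients informative
        self.head.b[...] = config.head_bias_init

    # -- parameter plumbing -------------------------------------------------
    def _layers(self) -> list[_Layer]:
        out: list[_Layer] = []
        for b in self.enc_blocks:
            out += b
        out += self.pools
        out += self.bottleneck
        out += self.ups
        for b in self.dec_blocks:
            out += b
        out.append(self.head)
        return out

    def parameters(self) -> list[tuple[_Layer, str]]:
        return [(layer, name) for layer in self._layers()
                for name in getattr(layer, "params", [])]

    def n_parameters(self) -> int:
        return sum(getattr(l, n).size for l, n in self.parameters())

    def zero_grad(self) -> None:
        for layer, name in self.parameters():
            getattr(layer, "g" + name).fill(0.0)

    # -- forward / backward -------------------------------------------------
    def _check_shape(self, shape) -> None:
        f = 2 ** self.config.depth
        if any(s % f for s in shape):
            raise UNetError(
                f"input spatial dims {tuple(shape)} must be divisible by "
                f"2^depth = {f}; pad the volume (e.g. np.pad to the next "
                f"multiple) before prediction")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N,1,D,H,W) float32 -> (N,1,D,H,W) foreground probability."""
        self._check_shape(x.shape[2:])
        skips = []
        h = x if x.dtype in (np.float32, np.float64) else x.astype(np.float32)
        h = np.ascontiguousarray(np.moveaxis(h, 1, -1))  # channels-last inside
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                h = layer.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        for layer in self.bottleneck:
            h = layer.forward(h, train)
        self._skip_ch = []
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h, train)
            self._skip_ch.append(skip.shape[-1])
            h = np.concatenate([skip, h], axis=-1)
            for layer in block:
                h = layer.forward(h, train)
        logits = self.head.forward(h, train)
        self._logits = logits if train else None
        return np.moveaxis(1.0 / (1.0 + np.exp(-logits)), -1, 1)

    def backward(self, dprob: np.ndarray) -> None:
        p = 1.0 / (1.0 + np.exp(-self._logits))
        grad = np.moveaxis(dprob, 1, -1) * p * (1.0 - p)
        grad = self.head.backward(grad)
        skip_grads = []
        for i in reversed(range(len(self.dec_blocks))):
            for layer in reversed(self.dec_blocks[i]):
                grad = layer.backward(grad)
            ch = self._skip_ch[i]
            skip_grads.append(grad[..., :ch])
            grad = np.ascontiguousarray(grad[..., ch:])
            grad = self.ups[i].backward(grad)
        for layer in reversed(self.bottleneck):
            grad = layer.backward(grad)
        skip_grads.reverse()  # now ordered from deepest encoder to shallowest
        for i in reversed(range(len(self.enc_blocks))):
            grad = self.pools[i].backward(grad)
            grad = grad + skip_grads[len(self.enc_blocks) - 1 - i]
            for layer in reversed(self.enc_blocks[i]):
                grad = layer.backward(grad)


def build_model(config: UNetConfig | None = None) -> UNet3D:
    """Construct an untrained U-Net from a config (defaults as documented)."""
    return UNet3D(config or UNetConfig())


# ---------------------------------------------------------------------------
# loss / optimiser / training

def _soft_dice(p: np.ndarray, g: np.ndarray, eps: float = 1e-6):
    """Per-batch soft Dice loss and its gradient wrt p."""
    axes = (1, 2, 3, 4)
    inter = (p * g).sum(axis=axes)
    denom = p.sum(axis=axes) + g.sum(axis=axes)
    dice = (2 * inter + eps) / (denom + eps)
    loss = float((1.0 - dice).mean())
    n = p.shape[0]
    ddice_dp = (2 * g * (denom + eps)[:, None, None, None, None]
                - (2 * inter + eps)[:, None, None, None, None]) \
        / ((denom + eps) ** 2)[:, None, None, None, None]
    return loss, -ddice_dp / n


def _bce(p: np.ndarray, g: np.ndarray, eps: float = 1e-7):
    pc = np.clip(p, eps, 1 - eps)
    loss = float(-(g * np.log(pc) + (1 - g) * np.log(1 - pc)).mean())
    grad = ((pc - g) / (pc * (1 - pc))) / p.size
    return loss, grad


class _Adam:
    def __init__(self, model: UNet3D, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = {id(l) * 7 + hash(n): (np.zeros_like(getattr(l, n)),
                                            np.zeros_like(getattr(l, n)))
                      for l, n in model.parameters()}

    def step(self) -> None:
        self.t += 1
        for layer, name in self.model.parameters():
            key = id(layer) * 7 + hash(name)
            m, v = self.state[key]
            g = getattr(layer, "g" + name)
            m[:] = self.beta1 * m + (1 - self.beta1) * g
            v[:] = self.beta2 * v + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            getattr(layer, name)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def znormalize(data: np.ndarray) -> np.ndarray:
    """Per-volume z-score normalisation (the model's expected input scale)."""
    data = data.astype(np.float32)
    sd = data.std()
    return (data - data.mean()) / (sd if sd > 0 else 1.0)


def hard_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = pred > 0, truth > 0
    s = pred.sum() + truth.sum()
    return 1.0 if s == 0 else 2.0 * (pred & truth).sum() / s


def train(
    model: UNet3D,
    subjects: list[tuple[LabeledVolume | np.ndarray, LabeledVolume | np.ndarray]],
    config: UNetConfig | None = None,
    target_dice: float | None = None,
    callback: Callable[[int, float, float], None] | None = None,
) -> tuple[UNet3D, list[dict]]:
    """Train on (volume, mask) pairs; returns (model, per-epoch history).

    History entries carry ``epoch``, ``loss`` and training ``dice`` (hard
    Dice at 0.5 on the epoch's forward passes). Deterministic for a fixed
    config seed. ``target_dice`` stops training early once the epoch's
    training Dice reaches the target (otherwise history length = epochs).
    """
    config = config or model.config
    if not subjects:
        raise UNetError("empty training set")
    xs, gs = [], []
    for vol, mask in subjects:
        v = vol.data if isinstance(vol, LabeledVolume) else np.asarray(vol)
        m = mask.data if isinstance(mask, LabeledVolume) else np.asarray(mask)
        if v.shape != m.shape:
            raise UNetError("volume/mask shape mismatch")
        if not np.isin(np.unique(m), (0, 1)).all():
            raise UNetError("training masks must be binary")
        xs.append(znormalize(v)[None])
        gs.append(m.astype(np.float32)[None])
    x = np.stack(xs)
    g = np.stack(gs)
    model._check_shape(x.shape[2:])

    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model, config.learning_rate)
    history: list[dict] = []
    n = len(subjects)
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, dices = [], []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            model.zero_grad()
            p = model.forward(x[idx], train=True)
            if config.loss == "dice":
                loss, dp = _soft_dice(p, g[idx])
            else:
                l1, d1 = _soft_dice(p, g[idx])
                l2, d2 = _bce(p, g[idx])
                loss, dp = l1 + l2, d1 + d2
            model.backward(dp)
            opt.step()
            losses.append(loss)
            dices.append(hard_dice(p > 0.5, g[idx]))
        ep = {"epoch": epoch, "loss": float(np.mean(losses)),
              "dice": float(np.mean(dices))}
        history.append(ep)
        if callback:
            callback(epoch, ep["loss"], ep["dice"])
        if target_dice is not None and ep["dice"] >= target_dice:
            break
    return model, history


def predict_mask(model: UNet3D, vol: LabeledVolume,
                 threshold: float = 0.5) -> LabeledVolume:
    """Binary foreground mask on ``vol``'s grid (probability > threshold)."""
    if not isinstance(vol, LabeledVolume):
        raise UNetError("predict_mask needs a LabeledVolume carrying geometry")
    x = znormalize(vol.data)[None, None]
    p = model.forward(x, train=False)[0, 0]
    return LabeledVolume((p > threshold).astype(np.uint8), vol.affine.copy())


# ---------------------------------------------------------------------------
# checkpoints (NumPy .npz + JSON config sidecar)

def save_checkpoint(model: UNet3D, path) -> None:
    import json
    from pathlib import Path
    arrays = {}
    for i, layer in enumerate(model._layers()):
        for name in getattr(layer, "params", []):
            arrays[f"{i}:{name}"] = getattr(layer, name)
        if isinstance(layer, _BatchNorm):
            arrays[f"{i}:run_mean"] = layer.run_mean
            arrays[f"{i}:run_var"] = layer.run_var
    np.savez(path, **arrays)
    cfg = model.config
    Path(str(path) + ".json").write_text(json.dumps(cfg.__dict__, indent=2))


def load_checkpoint(path) -> UNet3D:
    import json
    from pathlib import Path
    cfg = UNetConfig(**json.loads(Path(str(path) + ".json").read_text()))
    model = UNet3D(cfg)
    with np.load(path if str(path).endswith(".npz") else str(path)) as data:
        for i, layer in enumerate(model._layers()):
            for name in getattr(layer, "params", []):
                getattr(layer, name)[...] = data[f"{i}:{name}"]
            if isinstance(layer, _BatchNorm):
                layer.run_mean[...] = data[f"{i}:run_mean"]
                layer.run_var[...] = data[f"{i}:run_var"]
    return model
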