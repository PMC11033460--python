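"""A small symmetric encoder-decoder segmentation network in pure NumPy.

The canonical U-Net block structure is used: two 3x3 convolutions per level
(each followed by instance normalization and ReLU), 2x2 max-pooling on the
way down, nearest-neighbor upsampling followed by a 3x3 convolution on the
way up, skip concatenation, and a final 1x1 convolution with a per-object
sigmoid. Instance normalization keeps Dice-loss training stable at the
default learning rate of 1e-3; without it the plain conv/ReLU stack
saturates the sigmoid and gradients die. Forward and backward passes are
written by hand so the package has no deep-learning framework dependency;
the default full-scale configuration (base_filters=32, depth=5) widens the
filter count from 32 to 1024 at the bottleneck, while the desk-scale
configuration (base_filters=8, depth=3) trains in seconds on a CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "BackboneConfig",
    "UNet",
    "RMSprop",
    "build_backbone",
    "predict",
    "binarize",
    "dice_loss_and_grad",
]

_DTYPE = np.float32


@dataclass(frozen=True)
class BackboneConfig:
    in_channels: int
    out_objects: int
    base_filters: int = 32
    depth: int = 4
    norm: bool = True

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_objects < 1:
            raise ValueError("in_channels and out_objects must be >= 1")
        if self.base_filters < 1 or self.depth < 1:
            raise ValueError("base_filters and depth must be >= 1")

    @property
    def bottleneck_filters(self) -> int:
        return self.base_filters * 2**self.depth


# ---------------------------------------------------------------------------
# layer primitives (forward returns (out, cache))
# ---------------------------------------------------------------------------


def _conv_forward(x, W, b):
    k = W.shape[2]
    pad = k // 2
    if pad:
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    else:
        xp = x
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    out = np.einsum("nchwij,fcij->nfhw", win, W, optimize=True) + b[None, :, None, None]
    return out.astype(_DTYPE, copy=False), (win, W, x.shape)


def _conv_backward(dout, cache):
    win, W, xshape = cache
    n, c, h, w = xshape
    k = W.shape[2]
    pad = k // 2
    dW = np.einsum("nchwij,nfhw->fcij", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=_DTYPE)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += np.einsum(
                "nfhw,fc->nchw", dout, W[:, :, i, j], optimize=True
            )
    dx = dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp
    return dx, dW.astype(_DTYPE, copy=False), db.astype(_DTYPE, copy=False)


def _instnorm_forward(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=(2, 3), keepdims=True)
    var = x.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((x - mu) * inv).astype(_DTYPE)
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return out.astype(_DTYPE, copy=False), (xhat, inv.astype(_DTYPE), gamma)


def _instnorm_backward(dout, cache):
    xhat, inv, gamma = cache
    dgamma = (dout * xhat).sum(axis=(0, 2, 3))
    dbeta = dout.sum(axis=(0, 2, 3))
    dxhat = dout * gamma[None, :, None, None]
    m1 = dxhat.mean(axis=(2, 3), keepdims=True)
    m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return (
        dx.astype(_DTYPE, copy=False),
        dgamma.astype(_DTYPE, copy=False),
        dbeta.astype(_DTYPE, copy=False),
    )


def _relu_forward(x):
    return np.maximum(x, 0), x > 0


def _relu_backward(dout, cache):
    return dout * cache


def _pool_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    # ties share the gradient equally (deterministic)
    mask = xr == out[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5), keepdims=True)
    return out, (mask, counts, x.shape)


def _pool_backward(dout, cache):
    mask, counts, xshape = cache
    g = mask * (dout[:, :, :, None, :, None] / counts)
    return g.reshape(xshape).astype(_DTYPE, copy=False)


def _upsample_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3), x.shape


def _upsample_backward(dout, xshape):
    n, c, h, w = xshape
    return dout.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)).astype(_DTYPE, copy=False)


def _sigmoid(x):
    # clip keeps float32 exp finite; sigmoid(+-30) is saturated anyway
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def dice_loss_and_grad(probs: np.ndarray, truth: np.ndarray):
    """Mean per-object soft Dice L and the gradient of the minimized 1 - L.

    ``probs`` and ``truth`` have shape (N, K, H, W); an object absent from
    both maps contributes a Dice of 1 with zero gradient.
    """
    p = probs.astype(np.float64, copy=False)
    y = truth.astype(np.float64, copy=False)
    a = 2.0 * (p * y).sum(axis=(2, 3))
    b = (p * p).sum(axis=(2, 3)) + (y * y).sum(axis=(2, 3))
    safe_b = np.maximum(b, 1e-12)
    ds = np.where(b > 0, a / safe_b, 1.0)
    loss_score = float(ds.mean())
    scale = 1.0 / (p.shape[0] * p.shape[1])
    dl_dp = np.where(
        (b > 0)[:, :, None, None],
        (2.0 * y * b[:, :, None, None] - 2.0 * p * a[:, :, None, None])
        / (safe_b**2)[:, :, None, None],
        0.0,
    )
    grad = (-scale * dl_dp).astype(_DTYPE)
    return loss_score, grad


class UNet:
    """Trainable function (N, in_channels, H, W) -> (N, K, H, W) in [0, 1]."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        f = cfg.base_filters
        c_in = cfg.in_channels
        nm = cfg.norm
        for i in range(cfg.depth):
            c_out = f * 2**i
            self._init_conv(rng, f"enc{i}_c1", c_in, c_out, 3, normed=nm)
            self._init_conv(rng, f"enc{i}_c2", c_out, c_out, 3, normed=nm)
            c_in = c_out
        c_bot = cfg.bottleneck_filters
        self._init_conv(rng, "bot_c1", c_in, c_bot, 3, normed=nm)
        self._init_conv(rng, "bot_c2", c_bot, c_bot, 3, normed=nm)
        c_in = c_bot
        for i in reversed(range(cfg.depth)):
            c_skip = f * 2**i
            self._init_conv(rng, f"dec{i}_up", c_in, c_skip, 3, normed=nm)
            self._init_conv(rng, f"dec{i}_c1", 2 * c_skip, c_skip, 3, normed=nm)
            self._init_conv(rng, f"dec{i}_c2", c_skip, c_skip, 3, normed=nm)
            c_in = c_skip
        self._init_conv(rng, "head", c_in, cfg.out_objects, 1)
        self._cache = None

    def _init_conv(self, rng, name, c_in, c_out, k, normed=False):
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)
        self.params[f"{name}_W"] = rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(
            _DTYPE
        )
        self.params[f"{name}_b"] = np.zeros(c_out, dtype=_DTYPE)
        if normed:
            self.params[f"{name}_gamma"] = np.ones(c_out, dtype=_DTYPE)
            self.params[f"{name}_beta"] = np.zeros(c_out, dtype=_DTYPE)

    # -- forward / backward ------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) input, got shape {x.shape}")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels, model expects {self.cfg.in_channels}"
            )
        div = 2**self.cfg.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by 2**depth = {div}"
            )
        return x

    def _conv_relu(self, h, name, caches):
        h, cc = _conv_forward(h, self.params[f"{name}_W"], self.params[f"{name}_b"])
        ic = None
        if self.cfg.norm:
            h, ic = _instnorm_forward(
                h, self.params[f"{name}_gamma"], self.params[f"{name}_beta"]
            )
        h, rc = _relu_forward(h)
        caches[name] = (cc, ic, rc)
        return h

    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        x = self._check_input(x)
        caches: dict = {}
        skips = []
        h = x
        for i in range(self.cfg.depth):
            h = self._conv_relu(h, f"enc{i}_c1", caches)
            h = self._conv_relu(h, f"enc{i}_c2", caches)
            skips.append(h)
            h, pc = _pool_forward(h)
            caches[f"pool{i}"] = pc
        h = self._conv_relu(h, "bot_c1", caches)
        h = self._conv_relu(h, "bot_c2", caches)
        for i in reversed(range(self.cfg.depth)):
            h, us = _upsample_forward(h)
            caches[f"up{i}"] = us
            h = self._conv_relu(h, f"dec{i}_up", caches)
            h = np.concatenate([skips[i], h], axis=1)
            h = self._conv_relu(h, f"dec{i}_c1", caches)
            h = self._conv_relu(h, f"dec{i}_c2", caches)
        logits, hc = _conv_forward(h, self.params["head_W"], self.params["head_b"])
        probs = _sigmoid(logits).astype(_DTYPE)
        caches["head"] = hc
        caches["probs"] = probs
        self._cache = caches if keep_cache else None
        return probs

    def _conv_relu_backward(self, d, name, grads):
        cc, ic, rc = self._cache[name]
        d = _relu_backward(d, rc)
        if ic is not None:
            d, dgamma, dbeta = _instnorm_backward(d, ic)
            grads[f"{name}_gamma"] = dgamma
            grads[f"{name}_beta"] = dbeta
        d, dW, db = _conv_backward(d, cc)
        grads[f"{name}_W"] = dW
        grads[f"{name}_b"] = db
        return d

    def backward(self, dprobs: np.ndarray) -> dict[str, np.ndarray]:
        if self._cache is None:
            raise RuntimeError("forward(..., keep_cache=True) must be called first")
        caches = self._cache
        probs = caches["probs"]
        grads: dict[str, np.ndarray] = {}
        d = (dprobs * probs * (1.0 - probs)).astype(_DTYPE)
        d, dW, db = _conv_backward(d, caches["head"])
        grads["head_W"], grads["head_b"] = dW, db
        dskips = {}
        f = self.cfg.base_filters
        for i in range(self.cfg.depth):
            d = self._conv_relu_backward(d, f"dec{i}_c2", grads)
            d = self._conv_relu_backward(d, f"dec{i}_c1", grads)
            c_skip = f * 2**i
            dskips[i] = d[:, :c_skip]
            d = d[:, c_skip:]
            d = self._conv_relu_backward(d, f"dec{i}_up", grads)
            d = _upsample_backward(d, caches[f"up{i}"])
        d = self._conv_relu_backward(d, "bot_c2", grads)
        d = self._conv_relu_backward(d, "bot_c1", grads)
        for i in reversed(range(self.cfg.depth)):
            d = _pool_backward(d, caches[f"pool{i}"])
            d = d + dskips[i]
            d = self._conv_relu_backward(d, f"enc{i}_c2", grads)
            d = self._conv_relu_backward(d, f"enc{i}_c1", grads)
        self._cache = None
        return grads

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Dice score L on one batch plus parameter gradients of 1 - L."""
        probs = self.forward(x, keep_cache=True)
        score, dprobs = dice_loss_and_grad(probs, np.asarray(y, dtype=_DTYPE))
        grads = self.backward(dprobs)
        return score, grads

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, keep_cache=False)

    # -- state -------------------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k][...] = state[k]

    def save(self, path) -> None:
        np.savez(path, __config__=json.dumps(asdict(self.cfg)), **self.params)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path, allow_pickle=False) as data:
            cfg = BackboneConfig(**json.loads(str(data["__config__"])))
            model = cls(cfg, seed=0)
            model.set_state({k: data[k] for k in model.params})
        return model


class RMSprop:
    """RMSprop with standard parameterization (alpha 0.99, eps 1e-8)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.sq = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            sq = self.sq[k]
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            params[k] -= (self.lr * g / (np.sqrt(sq) + self.eps)).astype(params[k].dtype)


def build_backbone(cfg: BackboneConfig, seed: int = 0) -> UNet:
    """Construct a network; two builds with the same seed are bitwise equal."""
    return UNet(cfg, seed=seed)


def predict(model: UNet, images: np.ndarray) -> np.ndarray:
    """Probability maps for a (N, C, H, W) batch; no thresholding."""
    return model.predict(images)


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ties (p == threshold) go to foreground."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    p = np.asarray(p)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return p >= threshold
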