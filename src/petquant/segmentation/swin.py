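"""Swin-UNETR-topology segmentation network in plain numpy.

Encoder: non-overlapping patch embedding (default 2x2x2 patches to a
48-dimensional token), then ``n_stages`` repetitions of [two shifted-window
transformer blocks (W-MSA, then SW-MSA with a cyclic half-window shift) +
patch merging].  Each merge halves the token resolution per axis and doubles
the channel dimension.  Decoder: residual blocks of 3x3x3 convolutions with
instance normalization, nearest-neighbor upsampling, and skip concatenation
from the matching encoder stage; a stem residual block processes the raw
input at full resolution.  A final 1x1x1 convolution with softmax yields
per-voxel class probabilities.

All weights are drawn once from a seeded generator, so a fixed (seed, input)
pair gives a bit-reproducible forward pass.  The final linear head is the
network's trainable readout (see :mod:`petquant.segmentation.train`); the
feature stack feeding it also carries the raw intensity and normalized
voxel-coordinate channels, so spatially symmetric organs (left vs right
breast) remain separable by a linear readout.
"""

from __future__ import annotations

import numpy as np

from .config import SegmentationConfig

__all__ = ["SwinUnetr", "build_model"]


# ------------------------------------------------------------ primitive ops


def _dense(x, W, b):
    return x @ W + b


def _layer_norm(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * g + b


def _gelu(x):
    return 0.5 * x * (1.0 + np.tanh(np.sqrt(2.0 / np.pi) * (x + 0.044715 * x**3)))


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _conv3d(x, W, b):
    """x: (X,Y,Z,Cin); W: (k,k,k,Cin,Cout), k odd, 'same' zero padding."""
    k = W.shape[0]
    p = k // 2
    xp = np.pad(x, ((p, p), (p, p), (p, p), (0, 0)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(0, 1, 2))
    # view: (X,Y,Z,Cin,k,k,k)
    return np.einsum("xyzcijk,ijkco->xyzo", view, W, optimize=True) + b


def _instance_norm(x, g, b, eps=1e-5):
    mu = x.mean(axis=(0, 1, 2), keepdims=True)
    var = x.var(axis=(0, 1, 2), keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * g + b


def _upsample2(x):
    return x.repeat(2, axis=0).repeat(2, axis=1).repeat(2, axis=2)


def _window_for(res: int, window: int) -> int:
    """Largest divisor of ``res`` not exceeding ``window`` (so the token map
    tiles exactly into windows)."""
    w = min(window, res)
    while res % w:
        w -= 1
    return w


# -------------------------------------------------------------- param init


def _init_dense(rng, fan_in, fan_out):
    return rng.normal(0.0, 0.02, size=(fan_in, fan_out)), np.zeros(fan_out)


def _init_ln(dim):
    return np.ones(dim), np.zeros(dim)


def _init_conv(rng, k, cin, cout):
    scale = np.sqrt(2.0 / (k**3 * cin))
    return rng.normal(0.0, scale, size=(k, k, k, cin, cout)), np.zeros(cout)


def _init_block(rng, dim, mlp_ratio=4):
    p = {}
    p["ln1"] = _init_ln(dim)
    p["qkv"] = _init_dense(rng, dim, 3 * dim)
    p["proj"] = _init_dense(rng, dim, dim)
    p["ln2"] = _init_ln(dim)
    p["fc1"] = _init_dense(rng, dim, mlp_ratio * dim)
    p["fc2"] = _init_dense(rng, mlp_ratio * dim, dim)
    return p


def _init_resblock(rng, cin, cout):
    p = {}
    p["conv1"] = _init_conv(rng, 3, cin, cout)
    p["in1"] = _init_ln(cout)
    p["conv2"] = _init_conv(rng, 3, cout, cout)
    p["in2"] = _init_ln(cout)
    if cin != cout:
        p["skip"] = _init_conv(rng, 1, cin, cout)
    return p


# ------------------------------------------------------------- forward ops


def _attention(tokens, p, n_heads):
    """tokens: (nW, T, C) -> windowed multi-head self-attention."""
    nW, T, C = tokens.shape
    dh = C // n_heads
    qkv = _dense(tokens, *p["qkv"]).reshape(nW, T, 3, n_heads, dh)
    q, k, v = qkv[:, :, 0], qkv[:, :, 1], qkv[:, :, 2]  # (nW, T, H, dh)
    q = q.transpose(0, 2, 1, 3)  # (nW, H, T, dh)
    k = k.transpose(0, 2, 1, 3)
    v = v.transpose(0, 2, 1, 3)
    attn = _softmax(q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh), axis=-1)
    out = (attn @ v).transpose(0, 2, 1, 3).reshape(nW, T, C)
    return _dense(out, *p["proj"])


def _window_partition(x, w):
    r1, r2, r3, C = x.shape
    x = x.reshape(r1 // w, w, r2 // w, w, r3 // w, w, C)
    x = x.transpose(0, 2, 4, 1, 3, 5, 6)
    return x.reshape(-1, w**3, C)


def _window_reverse(tokens, w, shape):
    r1, r2, r3, C = shape
    x = tokens.reshape(r1 // w, r2 // w, r3 // w, w, w, w, C)
    x = x.transpose(0, 3, 1, 4, 2, 5, 6)
    return x.reshape(r1, r2, r3, C)


def _swin_block(x, p, window, n_heads, shifted):
    """One transformer block on a (R,R,R,C) token map; cyclic shift for SW-MSA."""
    w = _window_for(min(x.shape[:3]), window)
    s = w // 2 if (shifted and w > 1) else 0
    h = _layer_norm(x, *p["ln1"])
    if s:
        h = np.roll(h, shift=(-s, -s, -s), axis=(0, 1, 2))
    tokens = _window_partition(h, w)
    h = _window_reverse(_attention(tokens, p, n_heads), w, h.shape)
    if s:
        h = np.roll(h, shift=(s, s, s), axis=(0, 1, 2))
    x = x + h
    m = _layer_norm(x, *p["ln2"])
    m = _dense(_gelu(_dense(m, *p["fc1"])), *p["fc2"])
    return x + m


def _patch_merge(x, p):
    r1, r2, r3, C = x.shape
    x = x.reshape(r1 // 2, 2, r2 // 2, 2, r3 // 2, 2, C)
    x = x.transpose(0, 2, 4, 1, 3, 5, 6).reshape(r1 // 2, r2 // 2, r3 // 2, 8 * C)
    return _dense(_layer_norm(x, *p["ln"]), *p["reduce"])


def _resblock(x, p):
    h = np.maximum(_instance_norm(_conv3d(x, *p["conv1"]), *p["in1"]), 0.0)
    h = _instance_norm(_conv3d(h, *p["conv2"]), *p["in2"])
    skip = _conv3d(x, *p["skip"]) if "skip" in p else x
    return np.maximum(h + skip, 0.0)


# ------------------------------------------------------------------ network


class SwinUnetr:
    """Seeded random-weight Swin-UNETR; trainable softmax readout head."""

    def __init__(self, config: SegmentationConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        C, n = config.embed_dim, config.n_stages
        p: dict = {}
        p["embed"] = _init_dense(rng, config.patch_size**3, C)
        p["stages"] = []
        for i in range(n):
            dim = C * 2**i
            p["stages"].append(
                {
                    "block1": _init_block(rng, dim),
                    "block2": _init_block(rng, dim),
                    "merge": {"ln": _init_ln(8 * dim), "reduce": _init_dense(rng, 8 * dim, 2 * dim)},
                }
            )
        p["bottleneck"] = _init_resblock(rng, C * 2**n, C * 2**n)
        p["decoder"] = []
        for i in reversed(range(n)):
            cin = C * 2 ** (i + 1) + C * 2**i  # upsampled deeper stage + skip
            p["decoder"].append(_init_resblock(rng, cin, C * 2**i))
        p["stem"] = _init_resblock(rng, 1, C)
        p["final"] = _init_resblock(rng, 2 * C, C)
        self.params = p
        self.n_features = C + 4  # decoder output + raw intensity + 3 coords
        self.head_W = np.zeros((self.n_features, config.n_classes))
        self.head_b = np.zeros(config.n_classes)

    # -- architecture description (analytic; no forward pass required) ------

    def describe(self) -> list[dict]:
        """Token resolution (for a ``crop_size`` cube) and channel width at
        each encoder stage: resolution halves, channels double."""
        cfg = self.config
        r = cfg.crop_size // cfg.patch_size
        rows = [{"stage": "patch_embed", "token_resolution": r, "channels": cfg.embed_dim}]
        for i in range(cfg.n_stages):
            rows.append(
                {
                    "stage": f"merge_{i + 1}",
                    "token_resolution": r // 2 ** (i + 1),
                    "channels": cfg.embed_dim * 2 ** (i + 1),
                }
            )
        return rows

    def parameter_count(self) -> int:
        total = 0

        def walk(obj):
            nonlocal total
            if isinstance(obj, np.ndarray):
                total += obj.size
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self.params)
        return total + self.head_W.size + self.head_b.size

    # ------------------------------------------------------------- forward

    def _check_input(self, x: np.ndarray) -> None:
        stride = self.config.patch_size * 2**self.config.n_stages
        if x.ndim != 3 or any(d % stride for d in x.shape):
            raise ValueError(
                f"input shape {x.shape} incompatible: every axis must be a "
                f"multiple of patch_size * 2**n_stages = {stride}"
            )

    def forward_features(self, x: np.ndarray) -> np.ndarray:
        """Full-resolution per-voxel features, shape ``x.shape + (n_features,)``."""
        self._check_input(x)
        cfg, p = self.config, self.params
        ps = cfg.patch_size
        sx, sy, sz = (d // ps for d in x.shape)
        tokens = (
            x.reshape(sx, ps, sy, ps, sz, ps).transpose(0, 2, 4, 1, 3, 5).reshape(sx, sy, sz, ps**3)
        )
        h = _dense(tokens, *p["embed"])
        skips = []
        for i, stage in enumerate(p["stages"]):
            heads = max(1, h.shape[-1] // 16)
            h = _swin_block(h, stage["block1"], cfg.window_size, heads, shifted=False)
            h = _swin_block(h, stage["block2"], cfg.window_size, heads, shifted=True)
            skips.append(h)
            h = _patch_merge(h, stage["merge"])
        d = _resblock(h, p["bottleneck"])
        for dec, skip in zip(p["decoder"], reversed(skips)):
            d = _resblock(np.concatenate([_upsample2(d), skip], axis=-1), dec)
        while d.shape[0] < x.shape[0]:  # patch embedding stride
            d = _upsample2(d)
        stem = _resblock(x[..., None], p["stem"])
        d = _resblock(np.concatenate([d, stem], axis=-1), p["final"])
        coords = np.stack(
            np.meshgrid(*(np.linspace(-1, 1, n) for n in x.shape), indexing="ij"), axis=-1
        )
        return np.concatenate([d, x[..., None], coords], axis=-1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-voxel class probabilities, shape ``x.shape + (n_classes,)``;
        softmax guarantees they sum to one at every voxel."""
        return self.predict_proba_from_features(self.forward_features(x))

    def predict_proba_from_features(self, features: np.ndarray) -> np.ndarray:
        return _softmax(features @ self.head_W + self.head_b, axis=-1)

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(x), axis=-1)


def build_model(config: SegmentationConfig) -> SwinUnetr:
    """Construct the network for ``config`` (validated on construction)."""
    return SwinUnetr(config)
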