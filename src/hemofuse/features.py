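"""Fused feature extraction: capsule encoder + inverted-bottleneck encoder.

The classifier consumes the concatenation of two complementary image
descriptions:

* a desk-scale capsule network — convolution, primary capsules (vector
  units whose norm encodes presence and direction encodes pose), and a
  dynamic-routing step to entity capsules; the flattened entity capsules
  give the capsule-path vector (default 6 capsules x 31 dims = 186);
* a desk-scale inverted-bottleneck (MBConv-style) stack — pointwise
  expansion, depthwise convolution, pointwise compression with residual
  shortcuts, closed by a pointwise head and global average pooling
  (default 1000 dims).

Fusion is plain concatenation, giving q = n + m = 1186 features by
default, followed by entropy scoring: features whose histogram over the
sample set carries more Shannon entropy are kept, low-information
(near-constant) columns are dropped.

Both encoders run seeded-but-untrained by default: they are fixed random
projections in the random-features sense, deterministic given their seed.
Capsule transform weights are shared across spatial positions of each
primary-capsule map so that memory stays flat from 64x64 to 512x512.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit, softmax

__all__ = [
    "CapsEncoderConfig",
    "BottleneckEncoderConfig",
    "FusedFeatures",
    "squash",
    "dynamic_routing",
    "capsnet_encode",
    "capsnet_shape_trace",
    "bottleneck_encode",
    "inverted_bottleneck_block",
    "init_block_weights",
    "fuse_features",
    "column_entropy",
    "entropy_select",
]


# ---------------------------------------------------------------------------
# small conv toolbox (NumPy forward passes only)

def _conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """x: (C_in, H, W), w: (C_out, C_in, kh, kw) -> (C_out, H', W')."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    kh, kw = w.shape[2], w.shape[3]
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    # win: (C_in, H', W', kh, kw)
    return np.tensordot(w, win, axes=([1, 2, 3], [0, 3, 4]))


def _depthwise_conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """x: (C, H, W), w: (C, kh, kw) -> (C, H', W')."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    kh, kw = w.shape[1], w.shape[2]
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    return np.einsum("chwij,cij->chw", win, w)


def _swish(x: np.ndarray) -> np.ndarray:
    return x * expit(x)


def _channel_norm(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    mu = x.mean(axis=(1, 2), keepdims=True)
    var = x.var(axis=(1, 2), keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def _conv_out(size: int, kernel: int, stride: int, pad: int = 0) -> int:
    return (size + 2 * pad - kernel) // stride + 1


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


# ---------------------------------------------------------------------------
# capsule path

def squash(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """v -> (|v|^2 / (1 + |v|^2)) * v / |v|; zero maps to zero, norm < 1."""
    sq = np.sum(np.square(v), axis=axis, keepdims=True)
    scale = sq / (1.0 + sq) / np.sqrt(sq + 1e-300)
    return scale * v


def dynamic_routing(
    predictions: np.ndarray, iterations: int = 3, return_couplings: bool = False
):
    """Routing-by-agreement over prediction vectors.

    ``predictions`` has shape (n_in, n_out, dim).  Logits start at zero;
    each iteration takes the softmax over output capsules, forms the
    coupling-weighted sums, squashes them, and reinforces logits by the
    prediction/output agreement (dot product).
    """
    if iterations < 1:
        raise ValueError("routing iterations must be >= 1")
    u_hat = np.asarray(predictions, dtype=float)
    n_in, n_out, _ = u_hat.shape
    logits = np.zeros((n_in, n_out))
    coupling_trace = []
    v = None
    for _ in range(iterations):
        c = softmax(logits, axis=1)
        coupling_trace.append(c)
        s = np.einsum("ij,ijd->jd", c, u_hat)
        v = squash(s, axis=-1)
        logits = logits + np.einsum("ijd,jd->ij", u_hat, v)
    if return_couplings:
        return v, coupling_trace
    return v


@dataclass(frozen=True)
class CapsEncoderConfig:
    """Desk-scale capsule encoder.

    Defaults give a 186-dim capsule-path vector (6 entity capsules of
    dimension 31), the capsule half of the 1186-dim fused vector.
    """

    conv1_filters: int = 16
    conv1_kernel: int = 5
    conv1_stride: int = 2
    caps_maps: int = 4
    caps_dim: int = 4
    caps_kernel: int = 3
    caps_stride: int = 2
    entity_caps: int = 6
    entity_dim: int = 31
    routing_iterations: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.routing_iterations < 1:
            raise ValueError("routing iterations must be >= 1")
        if self.entity_caps < 1 or self.entity_dim < 1:
            raise ValueError("entity capsule count and dimension must be >= 1")

    @property
    def output_dim(self) -> int:
        return self.entity_caps * self.entity_dim


def capsnet_shape_trace(cfg: CapsEncoderConfig, height: int, width: int) -> dict:
    """Per-layer spatial shapes; raises with the trace if any collapses."""
    h1 = _conv_out(height, cfg.conv1_kernel, cfg.conv1_stride)
    w1 = _conv_out(width, cfg.conv1_kernel, cfg.conv1_stride)
    h2 = _conv_out(h1, cfg.caps_kernel, cfg.caps_stride)
    w2 = _conv_out(w1, cfg.caps_kernel, cfg.caps_stride)
    trace = {
        "input": (height, width),
        "conv1": (cfg.conv1_filters, h1, w1),
        "primary_caps": (cfg.caps_maps, h2, w2, cfg.caps_dim),
        "n_primary": cfg.caps_maps * h2 * w2,
        "entity_caps": (cfg.entity_caps, cfg.entity_dim),
        "output_dim": cfg.output_dim,
    }
    if min(h1, w1, h2, w2) < 1:
        raise ValueError(f"image too small for capsule encoder: {trace}")
    return trace


def _caps_weights(cfg: CapsEncoderConfig) -> dict:
    rng = np.random.default_rng(cfg.seed)
    w1 = _he(rng, (cfg.conv1_filters, 1, cfg.conv1_kernel, cfg.conv1_kernel),
             cfg.conv1_kernel**2)
    c_out = cfg.caps_maps * cfg.caps_dim
    w2 = _he(rng, (c_out, cfg.conv1_filters, cfg.caps_kernel, cfg.caps_kernel),
             cfg.conv1_filters * cfg.caps_kernel**2)
    # transform weights shared over spatial positions within a capsule map
    wt = _he(rng, (cfg.caps_maps, cfg.entity_caps, cfg.entity_dim, cfg.caps_dim),
             cfg.caps_dim)
    return {"conv1": w1, "primary": w2, "transform": wt}


def capsnet_encode(
    image: np.ndarray, cfg: CapsEncoderConfig | None = None, levels: int = 256
) -> np.ndarray:
    """Image -> flattened entity-capsule vector (length entity_caps*entity_dim)."""
    cfg = cfg or CapsEncoderConfig()
    cfg.validate()
    arr = np.asarray(image, dtype=float)
    trace = capsnet_shape_trace(cfg, *arr.shape)
    w = _caps_weights(cfg)

    x = (arr / (levels - 1))[None, :, :]
    x = np.maximum(_conv2d(x, w["conv1"], stride=cfg.conv1_stride), 0.0)
    x = _conv2d(x, w["primary"], stride=cfg.caps_stride)
    maps, h2, w2 = cfg.caps_maps, trace["primary_caps"][1], trace["primary_caps"][2]
    caps = x.reshape(maps, cfg.caps_dim, h2, w2).transpose(0, 2, 3, 1)
    caps = squash(caps.reshape(maps, h2 * w2, cfg.caps_dim), axis=-1)

    # predictions: capsule p of map g votes W[g, j] @ u_gp for entity capsule j
    u_hat = np.einsum("gjdc,gpc->gpjd", w["transform"], caps)
    u_hat = u_hat.reshape(maps * h2 * w2, cfg.entity_caps, cfg.entity_dim)
    v = dynamic_routing(u_hat, cfg.routing_iterations)
    return v.reshape(-1)


# ---------------------------------------------------------------------------
# inverted-bottleneck path

@dataclass(frozen=True)
class BottleneckEncoderConfig:
    """Desk-scale MBConv-style encoder ending in a 1000-dim pooled vector."""

    stem_filters: int = 8
    stem_kernel: int = 3
    stem_stride: int = 2
    stage_widths: tuple[int, ...] = (16, 24, 32)
    stage_strides: tuple[int, ...] = (2, 2, 2)
    expansion: int = 4
    output_dim: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.expansion < 1:
            raise ValueError("expansion factor must be >= 1")
        if self.output_dim < 1:
            raise ValueError("output dimension must be >= 1")
        if len(self.stage_widths) != len(self.stage_strides):
            raise ValueError("stage_widths and stage_strides must align")


def init_block_weights(
    rng: np.random.Generator, c_in: int, c_out: int, expansion: int, kernel: int = 3
) -> dict:
    mid = c_in * expansion
    return {
        "expand": _he(rng, (mid, c_in, 1, 1), c_in),
        "depthwise": _he(rng, (mid, kernel, kernel), kernel**2),
        "compress": _he(rng, (c_out, mid, 1, 1), mid),
    }


def inverted_bottleneck_block(
    x: np.ndarray, weights: dict, stride: int = 1
) -> np.ndarray:
    """Pointwise expand -> depthwise conv -> pointwise compress; residual
    shortcut when stride is 1 and channel counts match."""
    h = _swish(_conv2d(x, weights["expand"]))
    pad = weights["depthwise"].shape[-1] // 2
    h = _swish(_depthwise_conv2d(h, weights["depthwise"], stride=stride, pad=pad))
    h = _conv2d(h, weights["compress"])
    if stride == 1 and h.shape == x.shape:
        h = h + x
    return h


def bottleneck_encode(
    image: np.ndarray, cfg: BottleneckEncoderConfig | None = None, levels: int = 256
) -> np.ndarray:
    """Image -> globally pooled vector of length cfg.output_dim."""
    cfg = cfg or BottleneckEncoderConfig()
    cfg.validate()
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    rng = np.random.default_rng(cfg.seed)

    stem = _he(rng, (cfg.stem_filters, 1, cfg.stem_kernel, cfg.stem_kernel),
               cfg.stem_kernel**2)
    x = (arr / (levels - 1))[None, :, :]
    x = _conv2d(x, stem, stride=cfg.stem_stride, pad=cfg.stem_kernel // 2)
    x = _channel_norm(x)  # guarded: eps keeps zero input finite
    x = _swish(x)

    c_in = cfg.stem_filters
    for width, stride in zip(cfg.stage_widths, cfg.stage_strides):
        w = init_block_weights(rng, c_in, width, cfg.expansion)
        x = inverted_bottleneck_block(x, w, stride=stride)
        c_in = width
    # one stride-1 block at final width exercises the residual shortcut
    w = init_block_weights(rng, c_in, c_in, cfg.expansion)
    x = inverted_bottleneck_block(x, w, stride=1)

    head = _he(rng, (cfg.output_dim, c_in, 1, 1), c_in)
    x = _swish(_conv2d(x, head))
    if min(x.shape[1:]) < 1:
        raise ValueError(f"image too small for bottleneck encoder: {x.shape}")
    return x.mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# fusion and entropy-based selection

@dataclass
class FusedFeatures:
    """Concatenated capsule/bottleneck vector with its (n, m) provenance."""

    values: np.ndarray
    n: int
    m: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n + self.m:
            raise ValueError(
                f"fused length {self.values.size} != n + m = {self.n + self.m}"
            )

    def __len__(self) -> int:
        return self.values.size

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        return self.values[: self.n], self.values[self.n:]


def fuse_features(a: np.ndarray, b: np.ndarray) -> FusedFeatures:
    """Concatenate the capsule-path and bottleneck-path vectors verbatim."""
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("feature vectors must be finite")
    return FusedFeatures(np.concatenate([a, b]), a.size, b.size)


def column_entropy(matrix: np.ndarray, bins: int = 16) -> np.ndarray:
    """Shannon entropy (bits) of each column under equal-width binning
    over its observed range; constant columns score 0."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(matrix, dtype=float)
    ent = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        col = x[:, j]
        lo, hi = col.min(), col.max()
        if hi <= lo:
            continue
        counts, _ = np.histogram(col, bins=bins, range=(lo, hi))
        p = counts[counts > 0] / col.size
        ent[j] = float(-(p * np.log2(p)).sum())
    return ent


def entropy_select(matrix: np.ndarray, keep: int, bins: int = 16) -> np.ndarray:
    """Indices of the ``keep`` highest-entropy columns, ties to lower index."""
    x = np.asarray(matrix, dtype=float)
    if keep > x.shape[1]:
        raise ValueError(f"keep={keep} exceeds feature count {x.shape[1]}")
    ent = column_entropy(x, bins=bins)
    order = np.argsort(-ent, kind="stable")  # stable: ties keep lower index
    return np.sort(order[:keep])
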