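"""Parallel channel/spatial attention (P-CBAM) as a feature-map transform.

Works on plain ``(H, W, C)`` numpy arrays so the attention math can be
inspected and tested independently of the detector. The detector embeds the
same computation as a differentiable layer (:class:`polypdet.layers.PCBAM`);
a cross-check test asserts the two agree.

The block computes, from the same input F:

* channel attention  Mc(F) = σ(MLP(avgpool(F)) + MLP(maxpool(F))), pooling
  over space, MLP a shared two-layer bottleneck with reduction ratio r;
* spatial attention  Ms(F) = σ(f7×7(concat[avgpool(F), maxpool(F)])), pooling
  over channels, a 7×7 convolution with symmetric padding;

and fuses the gated maps Fc = Mc ⊙ F and Fs = Ms ⊙ F with a weighted residual:

    F_out = (α₁·Fc + α₂·Fs + α₃·F) / (α₁ + α₂ + α₃).

Unlike serial CBAM (channel gate, then spatial gate on the already-gated map),
both gates here see the original F — the two branches have equal priority.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate2d

__all__ = [
    "FusionWeights",
    "AttentionParams",
    "channel_attention",
    "spatial_attention",
    "pcbam_fuse",
    "pcbam_forward",
    "serial_cbam_forward",
]


def _check_feature_map(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError(f"feature map must be (H, W, C), got shape {f.shape}")
    if not np.isfinite(f).all():
        raise ValueError("feature map contains non-finite entries")
    return f


@dataclass(frozen=True)
class FusionWeights:
    """Nonnegative branch weights (channel, spatial, residual)."""

    alpha1: float = 1.0
    alpha2: float = 1.0
    alpha3: float = 1.0

    def __post_init__(self):
        a = (self.alpha1, self.alpha2, self.alpha3)
        if any(x < 0 for x in a):
            raise ValueError(f"fusion weights must be nonnegative, got {a}")
        if sum(a) <= 0:
            raise ValueError("at least one fusion weight must be positive")


@dataclass
class AttentionParams:
    """Parameters of one P-CBAM block.

    ``w1``/``b1``/``w2``/``b2`` form the shared channel bottleneck
    (C → max(C//r, 1) → C, ReLU between); ``spatial_kernel`` is (7, 7, 2)
    applied to the stacked channel-average and channel-max maps.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    spatial_kernel: np.ndarray
    spatial_bias: float = 0.0
    fusion: FusionWeights = field(default_factory=FusionWeights)

    @property
    def channels(self) -> int:
        return self.w1.shape[1]

    @classmethod
    def initialize(cls, channels: int, reduction: int = 16, kernel_size: int = 7,
                   seed: int = 0, fusion: FusionWeights | None = None) -> "AttentionParams":
        hidden = max(channels // reduction, 1)
        rng = np.random.default_rng(seed)
        w1 = rng.standard_normal((hidden, channels)) * np.sqrt(2.0 / channels)
        w2 = rng.standard_normal((channels, hidden)) * np.sqrt(2.0 / hidden)
        k = rng.standard_normal((kernel_size, kernel_size, 2)) * np.sqrt(2.0 / (2 * kernel_size**2))
        return cls(w1=w1, b1=np.zeros(hidden), w2=w2, b2=np.zeros(channels),
                   spatial_kernel=k, fusion=fusion or FusionWeights())

    @classmethod
    def identity_bottleneck(cls, channels: int, kernel: np.ndarray | None = None,
                            spatial_bias: float = 0.0,
                            fusion: FusionWeights | None = None) -> "AttentionParams":
        """No-reduction identity channel branch — handy for hand computation."""
        eye = np.eye(channels)
        k = np.zeros((7, 7, 2)) if kernel is None else np.asarray(kernel, dtype=float)
        return cls(w1=eye.copy(), b1=np.zeros(channels), w2=eye.copy(),
                   b2=np.zeros(channels), spatial_kernel=k, spatial_bias=spatial_bias,
                   fusion=fusion or FusionWeights())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # gates are strictly inside (0,1); keep that true even where the float
    # sigmoid saturates, by clipping to the nearest representable open values
    s = 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))
    return np.clip(s, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


def _bottleneck(params: AttentionParams, d: np.ndarray) -> np.ndarray:
    return params.w2 @ np.maximum(params.w1 @ d + params.b1, 0.0) + params.b2


def channel_attention(f: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Per-channel gate from globally pooled descriptors; shape (1, 1, C)."""
    f = _check_feature_map(f)
    avg = f.mean(axis=(0, 1))
    mx = f.max(axis=(0, 1))
    gate = _sigmoid(_bottleneck(params, avg) + _bottleneck(params, mx))
    return gate.reshape(1, 1, -1)


def spatial_attention(f: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Per-pixel gate from channel-pooled maps; shape (H, W, 1)."""
    f = _check_feature_map(f)
    avg = f.mean(axis=2)
    mx = f.max(axis=2)
    k = params.spatial_kernel
    resp = (correlate2d(avg, k[:, :, 0], mode="same", fillvalue=0.0)
            + correlate2d(mx, k[:, :, 1], mode="same", fillvalue=0.0)
            + params.spatial_bias)
    return _sigmoid(resp)[:, :, None]


def pcbam_fuse(f: np.ndarray, fc: np.ndarray, fs: np.ndarray,
               w: FusionWeights) -> np.ndarray:
    """Normalized weighted sum of the two gated maps and the residual input."""
    f, fc, fs = (np.asarray(x, dtype=float) for x in (f, fc, fs))
    if not (f.shape == fc.shape == fs.shape):
        raise ValueError(f"shape mismatch: F {f.shape}, Fc {fc.shape}, Fs {fs.shape}")
    total = w.alpha1 + w.alpha2 + w.alpha3
    return (w.alpha1 * fc + w.alpha2 * fs + w.alpha3 * f) / total


def pcbam_forward(f: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Full parallel block: both gates from the same F, then weighted fusion."""
    f = _check_feature_map(f)
    fc = channel_attention(f, params) * f
    fs = spatial_attention(f, params) * f
    return pcbam_fuse(f, fc, fs, params.fusion)


def serial_cbam_forward(f: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Serial CBAM reference: channel gate first, spatial gate on the result."""
    f = _check_feature_map(f)
    f1 = channel_attention(f, params) * f
    return spatial_attention(f1, params) * f1
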