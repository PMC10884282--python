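"""Neural building blocks for the detector, on top of :mod:`polypdet.autodiff`.

Blocks follow the CSP single-stage detector family: ``ConvBnSiLU`` units, the
C3 split-transform-concat block, the SPPF serial max-pooling pyramid, and the
parallel channel/spatial attention block (:class:`PCBAM`). All parameter
initialisation is driven by an explicit ``numpy.random.Generator`` so a seed
fully determines the model.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, batchnorm2d, concat, conv2d, maxpool2d

_SOFTPLUS_INV_1 = float(np.log(np.e - 1.0))  # softplus(x) = 1


class Module:
    """Tiny module base: parameter/buffer discovery and train/eval mode."""

    training: bool = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def named_buffers(self, prefix: str = ""):
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, np.ndarray):
                yield full, v
            elif isinstance(v, Tensor) and not v.requires_grad:
                yield full, v.data  # frozen parameters serialize as buffers
            elif isinstance(v, Module):
                yield from v.named_buffers(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.data.shape)
        for name, b in self.named_buffers():
            b[...] = state[name]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class ConvBnSiLU(Module):
    """k×k convolution + batch norm + SiLU; the basic unit of the backbone."""

    def __init__(self, rng, c1: int, c2: int, k: int = 1, s: int = 1, p: int | None = None):
        self.k, self.s = k, s
        self.p = k // 2 if p is None else p
        self.weight = Tensor(_kaiming(rng, (c2, c1, k, k), c1 * k * k), requires_grad=True)
        self.gamma = Tensor(np.ones(c2, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c2, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c2, dtype=np.float64)
        self.running_var = np.ones(c2, dtype=np.float64)

    def __call__(self, x: Tensor) -> Tensor:
        y = conv2d(x, self.weight, None, stride=self.s, padding=self.p)
        y = batchnorm2d(y, self.gamma, self.beta, self.running_mean, self.running_var,
                        training=self.training)
        return y.silu()


class Bottleneck(Module):
    def __init__(self, rng, c1: int, c2: int, shortcut: bool = True):
        self.cv1 = ConvBnSiLU(rng, c1, c2, 1, 1)
        self.cv2 = ConvBnSiLU(rng, c2, c2, 3, 1)
        self.add = shortcut and c1 == c2

    def __call__(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """CSP block: two 1×1 branches, one through n bottlenecks, concatenated."""

    def __init__(self, rng, c1: int, c2: int, n: int = 1, shortcut: bool = True):
        c_ = max(c2 // 2, 1)
        self.cv1 = ConvBnSiLU(rng, c1, c_, 1, 1)
        self.cv2 = ConvBnSiLU(rng, c1, c_, 1, 1)
        self.m = [Bottleneck(rng, c_, c_, shortcut) for _ in range(n)]
        self.cv3 = ConvBnSiLU(rng, 2 * c_, c2, 1, 1)

    def __call__(self, x: Tensor) -> Tensor:
        y1 = self.cv1(x)
        for b in self.m:
            y1 = b(y1)
        return self.cv3(concat([y1, self.cv2(x)], axis=1))


class SPPF(Module):
    """Serial 5×5 max-pool pyramid; equivalent to parallel SPP with 5/9/13."""

    def __init__(self, rng, c1: int, c2: int, k: int = 5):
        c_ = max(c1 // 2, 1)
        self.k = k
        self.cv1 = ConvBnSiLU(rng, c1, c_, 1, 1)
        self.cv2 = ConvBnSiLU(rng, 4 * c_, c2, 1, 1)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.cv1(x)
        y1 = maxpool2d(x, self.k, 1, self.k // 2)
        y2 = maxpool2d(y1, self.k, 1, self.k // 2)
        y3 = maxpool2d(y2, self.k, 1, self.k // 2)
        return self.cv2(concat([x, y1, y2, y3], axis=1))


class PCBAM(Module):
    """Parallel channel/spatial attention with a weighted residual fusion.

    Channel and spatial gates are computed from the same input (not chained as
    in serial CBAM) and the gated maps are fused as a normalized weighted sum
    ``(α1·Fc + α2·Fs + α3·F) / (α1+α2+α3)``. The fusion weights are learnable
    scalars kept positive through a softplus reparameterisation, initialised so
    each weight starts at 1; ``learn_alphas=False`` freezes them there.
    """

    def __init__(self, rng, c: int, reduction: int = 16, learn_alphas: bool = True):
        hidden = max(c // reduction, 1)
        self.w1 = Tensor(_kaiming(rng, (hidden, c), c), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden, dtype=np.float32), requires_grad=True)
        self.w2 = Tensor(_kaiming(rng, (c, hidden), hidden), requires_grad=True)
        self.b2 = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.spatial_w = Tensor(_kaiming(rng, (1, 2, 7, 7), 2 * 49), requires_grad=True)
        self.spatial_b = Tensor(np.zeros(1, dtype=np.float32), requires_grad=True)
        self.alpha_raw = Tensor(np.full(3, _SOFTPLUS_INV_1, dtype=np.float32),
                                requires_grad=learn_alphas)

    def _mlp(self, d: Tensor) -> Tensor:
        h = (d @ self.w1.transpose(1, 0) + self.b1).relu()
        return h @ self.w2.transpose(1, 0) + self.b2

    def channel_gate(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        return (self._mlp(avg) + self._mlp(mx)).sigmoid().reshape(n, c, 1, 1)

    def spatial_gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        m = conv2d(concat([avg, mx], axis=1), self.spatial_w, self.spatial_b, 1, 3)
        return m.sigmoid()

    def alphas(self) -> Tensor:
        # softplus keeps the fusion weights strictly positive
        return (self.alpha_raw.exp() + 1.0).log()

    def __call__(self, x: Tensor) -> Tensor:
        fc = self.channel_gate(x) * x
        fs = self.spatial_gate(x) * x
        a = self.alphas()
        a1, a2, a3 = a[0], a[1], a[2]
        return (a1 * fc + a2 * fs + a3 * x) / (a1 + a2 + a3)


class HeadConv(Module):
    """1×1 prediction convolution: bias, no norm, no activation."""

    def __init__(self, rng, c1: int, c2: int, prior_prob: float = 0.01):
        self.weight = Tensor(_kaiming(rng, (c2, c1, 1, 1), c1) * 0.1, requires_grad=True)
        self.bias = Tensor(np.zeros(c2, dtype=np.float32), requires_grad=True)
        self._prior = prior_prob

    def set_objectness_prior(self, na: int, no: int) -> None:
        """Bias objectness logits so the initial background score is low."""
        b = self.bias.data.reshape(na, no)
        b[:, 4] = float(np.log(self._prior / (1.0 - self._prior)))
        self.bias.data = b.reshape(-1)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, 1, 0)


class Adam:
    """Adam with decoupled parameter list; state keyed by parameter identity."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            upd = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = (p.data - self.lr * upd).astype(p.data.dtype)
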