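"""Neural-network layers and the Adam optimizer, built on the autodiff engine.

Layers follow the conventions of the diffusion-model literature: 3x3
convolutions with SiLU nonlinearities, group normalization, multi-head
self-attention over flattened spatial positions, strided convolution for
downsampling and transposed convolution for upsampling.  Weights are
initialized from seeded Gaussians scaled by fan-in; biases start at zero.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, im2col

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "GroupNorm",
    "SelfAttention2d",
    "ResBlock",
    "Adam",
    "num_groups_for",
]

DTYPE = np.float32


def num_groups_for(channels: int, preferred: int = 8) -> int:
    """Largest divisor of ``channels`` that does not exceed ``preferred``."""
    for g in range(min(preferred, channels), 0, -1):
        if channels % g == 0:
            return g
    return 1


class Module:
    """Minimal parameter container with recursive traversal."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        super().__setattr__(name, value)

    def _register(self, name: str, data: np.ndarray) -> Tensor:
        p = Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)
        self._params[name] = p
        return p

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for mname, mod in self._modules.items():
            out.extend(mod.named_parameters(prefix + mname + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        std = 1.0 / np.sqrt(in_features)
        self.w = self._register("w", rng.normal(0.0, std, (in_features, out_features)))
        self.b = self._register("b", np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    """2-D convolution via im2col; symmetric zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, zero_init: bool = False):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = in_ch * kernel * kernel
        w0 = np.zeros((out_ch, fan_in)) if zero_init else rng.normal(
            0.0, 1.0 / np.sqrt(fan_in), (out_ch, fan_in)
        )
        self.w = self._register("w", w0)
        self.b = self._register("b", np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        oh = (H + 2 * p - k) // s + 1
        ow = (W + 2 * p - k) // s + 1
        cols = im2col(x.pad2d(p), k, s)            # (C*k*k, B*oh*ow)
        out = self.w @ cols                        # one GEMM: (out_ch, B*oh*ow)
        out = out.reshape(self.out_ch, B, oh, ow).transpose(1, 0, 2, 3)
        return out + self.b.reshape(1, self.out_ch, 1, 1)


class ConvTranspose2d(Module):
    """Transposed convolution, kernel 2 stride 2 (exact 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch
        self.w = self._register(
            "w", rng.normal(0.0, 1.0 / np.sqrt(fan_in), (out_ch * 4, in_ch))
        )
        self.b = self._register("b", np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        flat = x.transpose(1, 0, 2, 3).reshape(C, B * H * W)
        out = self.w @ flat                                      # (O*4, B*H*W)
        out = out.reshape(self.out_ch, 2, 2, B, H, W)
        out = out.transpose(3, 0, 4, 1, 5, 2)                    # (B, O, H, 2, W, 2)
        out = out.reshape(B, self.out_ch, 2 * H, 2 * W)
        return out + self.b.reshape(1, self.out_ch, 1, 1)


class GroupNorm(Module):
    def __init__(self, channels: int, groups: int | None = None, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.groups = num_groups_for(channels) if groups is None else groups
        if channels % self.groups:
            raise ValueError(f"groups {self.groups} must divide channels {channels}")
        self.eps = eps
        self.gamma = self._register("gamma", np.ones(channels))
        self.beta = self._register("beta", np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        g = self.groups
        xg = x.reshape(B, g, (C // g) * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        d = xg - mu
        var = (d * d).mean(axis=2, keepdims=True)
        xn = d * (var + self.eps).pow(-0.5)
        xn = xn.reshape(B, C, H, W)
        return xn * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class SelfAttention2d(Module):
    """Multi-head self-attention over spatial positions, with residual add."""

    def __init__(self, channels: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        if channels % num_heads:
            raise ValueError(f"num_heads {num_heads} must divide channels {channels}")
        self.channels, self.num_heads = channels, num_heads
        self.head_dim = channels // num_heads
        self.norm = GroupNorm(channels)
        self.qkv = Conv2d(channels, 3 * channels, 1, rng)
        self.proj = Conv2d(channels, channels, 1, rng, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        nh, hd, L = self.num_heads, self.head_dim, H * W
        qkv = self.qkv(self.norm(x)).reshape(B, 3, nh, hd, L)
        q = qkv[:, 0].transpose(0, 1, 3, 2)          # (B, nh, L, hd)
        k = qkv[:, 1]                                # (B, nh, hd, L)
        v = qkv[:, 2].transpose(0, 1, 3, 2)          # (B, nh, L, hd)
        attn = ((q * (hd ** -0.5)) @ k).softmax()    # (B, nh, L, L)
        out = (attn @ v).transpose(0, 1, 3, 2).reshape(B, C, H, W)
        return x + self.proj(out)


class ResBlock(Module):
    """Pre-activation residual block with additive timestep conditioning."""

    def __init__(self, in_ch: int, out_ch: int, time_dim: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.norm1 = GroupNorm(in_ch)
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, padding=1)
        self.time_proj = Linear(time_dim, out_ch, rng)
        self.norm2 = GroupNorm(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, padding=1)
        self.skip = Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def __call__(self, x: Tensor, temb: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x).silu())
        tproj = self.time_proj(temb.silu())
        h = h + tproj.reshape(tproj.shape[0], self.out_ch, 1, 1)
        h = self.conv2(self.norm2(h).silu())
        res = x if self.skip is None else self.skip(x)
        return h + res


class Adam:
    """Adam with bias correction; operates in-place on parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

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
            p.data -= (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
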