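"""The trainable noise predictor eps_theta(x_t, t).

A compact U-Net conditioned on the diffusion timestep through sinusoidal
position embeddings.  The encoder applies, per resolution level, a fixed
number of residual blocks followed by multi-head self-attention and a strided
convolution down; the bottleneck interleaves residual blocks with attention;
the decoder mirrors the encoder with skip concatenation and transposed-
convolution upsampling; a final residual block and a zero-initialized 3x3
convolution produce the noise estimate at the input resolution.

Timesteps are 1-based, matching the schedule convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .images import Domain, ImageBatch
from .nn import Conv2d, ConvTranspose2d, GroupNorm, Linear, Module, ResBlock, SelfAttention2d
from .schedules import NoiseSchedule

__all__ = [
    "DenoiserSpec",
    "UNetDenoiser",
    "sinusoidal_time_embedding",
    "build_denoiser",
    "denoise",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT = "chestdiff-checkpoint-1"


@dataclass(frozen=True)
class DenoiserSpec:
    """Architecture hyperparameters of the U-Net noise predictor."""

    base_channels: int = 28
    channel_multipliers: tuple[int, ...] = (1, 2, 4)
    blocks_per_stage: int = 2
    time_embedding_dim: int = 56
    attention_levels: tuple[int, ...] = (0, 1, 2)
    num_heads: int = 4
    image_size: int = 28

    def __post_init__(self):
        if self.base_channels < 1 or self.blocks_per_stage < 1 or self.num_heads < 1:
            raise ValueError("base_channels, blocks_per_stage, num_heads must be positive")
        if self.time_embedding_dim % 2:
            raise ValueError("time_embedding_dim must be even (sin/cos halves)")
        if any(m < 1 for m in self.channel_multipliers):
            raise ValueError("channel multipliers must be positive")
        down_factor = 2 ** (len(self.channel_multipliers) - 1)
        if self.image_size % down_factor:
            raise ValueError(
                f"image size {self.image_size} must be divisible by {down_factor} "
                f"for {len(self.channel_multipliers)} resolution levels"
            )
        bad = [l for l in self.attention_levels
               if not 0 <= l < len(self.channel_multipliers)]
        if bad:
            raise ValueError(f"attention_levels out of range: {bad}")
        for m in self.channel_multipliers:
            if (self.base_channels * m) % self.num_heads:
                raise ValueError(
                    f"num_heads {self.num_heads} must divide every stage width; "
                    f"{self.base_channels * m} fails"
                )

    def to_config(self) -> dict:
        d = asdict(self)
        d["channel_multipliers"] = list(self.channel_multipliers)
        d["attention_levels"] = list(self.attention_levels)
        return d

    @staticmethod
    def from_config(cfg: dict) -> "DenoiserSpec":
        cfg = dict(cfg)
        for key in ("channel_multipliers", "attention_levels"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return DenoiserSpec(**cfg)


def sinusoidal_time_embedding(t, dim: int) -> np.ndarray:
    """Sinusoidal position embedding of timestep(s) ``t``.

    The first dim/2 entries are sin(t * w_k), the last dim/2 are cos(t * w_k),
    with frequencies w_k geometrically spaced from 1 down to 1/10000.
    Accepts a scalar (returns shape (dim,)) or an array of timesteps
    (returns shape (len(t), dim)).
    """
    if dim % 2 or dim < 2:
        raise ValueError(f"dim must be even and >= 2, got {dim}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    if np.any(t_arr < 0):
        raise ValueError("timesteps must be non-negative")
    half = dim // 2
    if half == 1:
        freqs = np.ones(1)
    else:
        freqs = np.exp(-np.log(10000.0) * np.arange(half) / (half - 1))
    angles = t_arr[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(angles), np.cos(angles)], axis=1)
    return emb[0] if np.isscalar(t) or np.ndim(t) == 0 else emb


class UNetDenoiser(Module):
    """Shape-preserving noise predictor; see module docstring."""

    def __init__(self, spec: DenoiserSpec, rng_seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(rng_seed)
        chs = [spec.base_channels * m for m in spec.channel_multipliers]
        tdim = spec.time_embedding_dim
        L = len(chs)

        self.time_mlp1 = Linear(tdim, tdim * 2, rng)
        self.time_mlp2 = Linear(tdim * 2, tdim, rng)
        self.stem = Conv2d(1, chs[0], 3, rng, padding=1)

        self._down_blocks: list[list[ResBlock]] = []
        self._down_attn: list[SelfAttention2d | None] = []
        self._downsample: list[Conv2d | None] = []
        cur = chs[0]
        for lvl in range(L):
            blocks = []
            for b in range(spec.blocks_per_stage):
                blk = ResBlock(cur, chs[lvl], tdim, rng)
                setattr(self, f"down{lvl}_block{b}", blk)
                blocks.append(blk)
                cur = chs[lvl]
            self._down_blocks.append(blocks)
            if lvl in spec.attention_levels:
                attn = SelfAttention2d(cur, spec.num_heads, rng)
                setattr(self, f"down{lvl}_attn", attn)
                self._down_attn.append(attn)
            else:
                self._down_attn.append(None)
            if lvl < L - 1:
                ds = Conv2d(cur, cur, 3, rng, stride=2, padding=1)
                setattr(self, f"down{lvl}_downsample", ds)
                self._downsample.append(ds)
            else:
                self._downsample.append(None)

        self.mid_block1 = ResBlock(cur, cur, tdim, rng)
        self.mid_attn = SelfAttention2d(cur, spec.num_heads, rng)
        self.mid_block2 = ResBlock(cur, cur, tdim, rng)

        self._up_blocks: list[list[ResBlock]] = []
        self._up_attn: list[SelfAttention2d | None] = []
        self._upsample: list[ConvTranspose2d | None] = []
        for lvl in range(L - 1, -1, -1):
            blocks = []
            in_ch = cur + chs[lvl]  # skip concatenation
            for b in range(spec.blocks_per_stage):
                blk = ResBlock(in_ch, chs[lvl], tdim, rng)
                setattr(self, f"up{lvl}_block{b}", blk)
                blocks.append(blk)
                in_ch = chs[lvl]
            cur = chs[lvl]
            self._up_blocks.append(blocks)
            if lvl in spec.attention_levels:
                attn = SelfAttention2d(cur, spec.num_heads, rng)
                setattr(self, f"up{lvl}_attn", attn)
                self._up_attn.append(attn)
            else:
                self._up_attn.append(None)
            if lvl > 0:
                us = ConvTranspose2d(cur, chs[lvl - 1], rng)
                setattr(self, f"up{lvl}_upsample", us)
                self._upsample.append(us)
                cur = chs[lvl - 1]
            else:
                self._upsample.append(None)

        self.final_block = ResBlock(cur, cur, tdim, rng)
        self.out_norm = GroupNorm(cur)
        self.out_conv = Conv2d(cur, 1, 3, rng, padding=1, zero_init=True)

    # -- forward ---------------------------------------------------------------
    def forward(self, xt: Tensor, t: np.ndarray, *, _ablate_skips: bool = False) -> Tensor:
        """Predict the corrupting noise from (x_t, t); t is 1-based, per-image."""
        B = xt.shape[0]
        t_arr = np.broadcast_to(np.atleast_1d(np.asarray(t)), (B,))
        emb = sinusoidal_time_embedding(t_arr.astype(np.float64), self.spec.time_embedding_dim)
        temb = Tensor(emb.astype(xt.data.dtype))
        temb = self.time_mlp2(self.time_mlp1(temb).silu())

        h = self.stem(xt)
        skips: list[Tensor] = []
        for lvl, blocks in enumerate(self._down_blocks):
            for blk in blocks:
                h = blk(h, temb)
            if self._down_attn[lvl] is not None:
                h = self._down_attn[lvl](h)
            skips.append(h)
            if self._downsample[lvl] is not None:
                h = self._downsample[lvl](h)

        h = self.mid_block1(h, temb)
        h = self.mid_attn(h)
        h = self.mid_block2(h, temb)

        for i, blocks in enumerate(self._up_blocks):
            skip = skips.pop()
            if _ablate_skips:
                skip = Tensor(np.zeros_like(skip.data))
            h = concat([h, skip], axis=1)
            for blk in blocks:
                h = blk(h, temb)
            if self._up_attn[i] is not None:
                h = self._up_attn[i](h)
            if self._upsample[i] is not None:
                h = self._upsample[i](h)

        h = self.final_block(h, temb)
        return self.out_conv(self.out_norm(h).silu())

    __call__ = forward


def build_denoiser(spec: DenoiserSpec, rng_seed: int = 0) -> UNetDenoiser:
    """Construct a U-Net; identical seeds yield bitwise-identical parameters."""
    return UNetDenoiser(spec, rng_seed)


def denoise(model: UNetDenoiser, xt: ImageBatch, t) -> np.ndarray:
    """Inference-mode noise prediction; returns an array of x_t's shape."""
    if isinstance(xt, ImageBatch):
        if xt.domain is Domain.UINT8:
            raise ValueError("denoise expects NORMALIZED input; call normalize() first")
        pixels = xt.pixels
    else:
        pixels = np.asarray(xt)
    with no_grad():
        out = model(Tensor(pixels.astype(np.float32, copy=False)), t)
    return out.data


# ---------------------------------------------------------------------------
# Checkpoints: one NPZ holding parameters + JSON metadata
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: UNetDenoiser, schedule: NoiseSchedule,
                    metadata: dict | None = None) -> Path:
    """Persist parameters, architecture, schedule, and run metadata."""
    meta = {
        "format": CHECKPOINT_FORMAT,
        "spec": model.spec.to_config(),
        "schedule": schedule.to_config(),
        "run": metadata or {},
    }
    arrays = {f"param:{k}": v for k, v in model.state_dict().items()}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path) -> tuple[UNetDenoiser, NoiseSchedule, dict]:
    """Rebuild (model, schedule, run metadata) from a checkpoint file."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(
                f"unrecognized checkpoint format {meta.get('format')!r}; "
                f"expected {CHECKPOINT_FORMAT!r}"
            )
        state = {k[len("param:"):]: archive[k] for k in archive.files
                 if k.startswith("param:")}
    spec = DenoiserSpec.from_config(meta["spec"])
    model = UNetDenoiser(spec, rng_seed=0)
    model.load_state_dict(state)
    schedule = NoiseSchedule.from_config(meta["schedule"])
    return model, schedule, meta["run"]
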