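"""Noise schedules for the diffusion forward/reverse processes.

A schedule fixes, for every timestep t = 1..T, the corruption intensity
beta_t, the signal retention alpha_t = 1 - beta_t, the cumulative signal
fraction alpha_bar_t = prod_{s<=t} alpha_s, and the reverse-step noise scale
sigma_t.  All constants are precomputed once at construction.

Timesteps are 1-based at every public boundary (t = 1..T); internal arrays
are 0-based, so element ``i`` holds the constants for step ``t = i + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = ["NoiseSchedule", "make_linear_schedule", "schedule_constants_at", "StepConstants"]

SigmaVariant = Literal["beta", "posterior"]


@dataclass(frozen=True)
class NoiseSchedule:
    """Precomputed per-step diffusion constants for t = 1..T."""

    T: int
    betas: np.ndarray
    alphas: np.ndarray
    alpha_bars: np.ndarray
    sigmas: np.ndarray
    sigma_variant: str = "beta"
    beta_start: float = field(default=float("nan"), compare=False)
    beta_end: float = field(default=float("nan"), compare=False)

    def __post_init__(self):
        for name in ("betas", "alphas", "alpha_bars", "sigmas"):
            arr = getattr(self, name)
            if len(arr) != self.T:
                raise ValueError(f"{name} must have length T={self.T}, got {len(arr)}")
        if not np.allclose(self.alphas, 1.0 - self.betas, rtol=0, atol=0):
            raise ValueError("alphas must equal 1 - betas exactly")
        if np.any(self.alpha_bars <= 0) or np.any(self.alpha_bars >= 1):
            raise ValueError("alpha_bars must lie in (0, 1)")
        if self.T > 1 and np.any(np.diff(self.alpha_bars) >= 0):
            raise ValueError("alpha_bars must be strictly decreasing")
        if np.any(self.sigmas**2 > self.betas * (1 + 1e-12)):
            raise ValueError("sigma_t^2 must not exceed beta_t")

    def to_config(self) -> dict:
        """Serializable schedule parameters (run-configuration keys)."""
        return {
            "T": self.T,
            "beta_start": float(self.beta_start),
            "beta_end": float(self.beta_end),
            "sigma_variant": self.sigma_variant,
        }

    @staticmethod
    def from_config(cfg: dict) -> "NoiseSchedule":
        return make_linear_schedule(
            int(cfg["T"]),
            float(cfg["beta_start"]),
            float(cfg["beta_end"]),
            sigma_variant=cfg.get("sigma_variant", "beta"),
        )


@dataclass(frozen=True)
class StepConstants:
    """The constants of a single timestep, queried through 1-based t."""

    beta: float
    alpha: float
    alpha_bar: float
    sigma: float
    sqrt_alpha_bar: float
    sqrt_one_minus_alpha_bar: float


def make_linear_schedule(
    T: int,
    beta_start: float = 1e-4,
    beta_end: float = 0.02,
    sigma_variant: SigmaVariant = "beta",
) -> NoiseSchedule:
    """Build a schedule with betas evenly spaced from beta_start to beta_end.

    Parameters
    ----------
    T : int
        Number of diffusion steps (>= 1).  ``T == 1`` degenerates to a single
        beta equal to ``beta_start``.
    beta_start, beta_end : float
        Inclusive endpoints of the linear ramp; require
        ``0 < beta_start <= beta_end < 1``.
    sigma_variant : {"beta", "posterior"}
        Reverse-step noise variance: ``sigma_t^2 = beta_t`` (default), or the
        posterior variance ``beta_t * (1 - alpha_bar_{t-1}) / (1 - alpha_bar_t)``
        (with ``alpha_bar_0 := 1``, so ``sigma_1 = 0``).
    """
    if not isinstance(T, (int, np.integer)) or T < 1:
        raise ValueError(f"T must be a positive integer, got {T!r}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError(
            f"require 0 < beta_start <= beta_end < 1, got ({beta_start}, {beta_end})"
        )
    if sigma_variant not in ("beta", "posterior"):
        raise ValueError(f"unknown sigma_variant {sigma_variant!r}")

    if T == 1:
        betas = np.array([beta_start], dtype=np.float64)
    else:
        betas = np.linspace(beta_start, beta_end, T, dtype=np.float64)
    alphas = 1.0 - betas
    alpha_bars = np.cumprod(alphas)
    if sigma_variant == "beta":
        sigmas = np.sqrt(betas)
    else:
        prev = np.concatenate([[1.0], alpha_bars[:-1]])
        sigmas = np.sqrt(betas * (1.0 - prev) / (1.0 - alpha_bars))
    return NoiseSchedule(
        T=int(T),
        betas=betas,
        alphas=alphas,
        alpha_bars=alpha_bars,
        sigmas=sigmas,
        sigma_variant=sigma_variant,
        beta_start=float(beta_start),
        beta_end=float(beta_end),
    )


def schedule_constants_at(s: NoiseSchedule, t: int) -> StepConstants:
    """Return the precomputed constants at 1-based timestep ``t``.

    Raises
    ------
    IndexError
        If ``t`` is outside 1..T; the message names the valid range.
    """
    if not (1 <= t <= s.T):
        raise IndexError(f"timestep {t} out of range; valid timesteps are 1..{s.T}")
    i = t - 1
    ab = float(s.alpha_bars[i])
    return StepConstants(
        beta=float(s.betas[i]),
        alpha=float(s.alphas[i]),
        alpha_bar=ab,
        sigma=float(s.sigmas[i]),
        sqrt_alpha_bar=float(np.sqrt(ab)),
        sqrt_one_minus_alpha_bar=float(np.sqrt(1.0 - ab)),
    )
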