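"""Forward corruption, training loss, and single-step reverse update.

The forward (corruption) process draws

    x_t = sqrt(alpha_bar_t) * x_0 + sqrt(1 - alpha_bar_t) * eps,   eps ~ N(0, I),

the network is trained to predict eps from (x_t, t), and the ancestral
reverse update reconstructs

    x_{t-1} = (1 / sqrt(alpha_t)) * (x_t - beta_t / sqrt(1 - alpha_bar_t) * eps_hat)
              + sigma_t * z,

with the noise term suppressed at t = 1 (the deterministic last step).

Loss scalings: L2 is the plain mean square (no 1/2 factor); the Huber
quadratic branch carries the 1/2, so Huber -> (1/2) * L2 as delta -> inf.
Loss-curve magnitudes depend on these conventions.
"""

from __future__ import annotations

import enum

import numpy as np

from .images import Domain, ImageBatch
from .schedules import NoiseSchedule, schedule_constants_at

__all__ = [
    "LossKind",
    "q_sample",
    "predict_x0",
    "p_sample_step",
    "noise_prediction_loss",
]


class LossKind(enum.Enum):
    L1 = "l1"
    L2 = "l2"
    HUBER = "huber"

    @classmethod
    def parse(cls, value) -> "LossKind":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).upper()] if str(value).upper() in cls.__members__ \
                else cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown loss kind {value!r}; choose from "
                f"{[k.name for k in cls]}"
            ) from None


def _as_pixels(x, name: str) -> np.ndarray:
    if isinstance(x, ImageBatch):
        if x.domain is Domain.UINT8:
            raise ValueError(
                f"{name} is in the UINT8 domain; normalize() it to [-1, 1] first"
            )
        return x.pixels
    return np.asarray(x)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def _step_factors(t, s: NoiseSchedule, batch: int):
    """Per-element sqrt(alpha_bar_t), sqrt(1 - alpha_bar_t) broadcast over a batch.

    ``t`` may be a scalar timestep or a length-batch array of timesteps
    (1-based).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.int64))
    if t_arr.size == 1:
        t_arr = np.full(batch, int(t_arr[0]), dtype=np.int64)
    if t_arr.shape != (batch,):
        raise ValueError(f"t must be scalar or length-{batch}, got shape {t_arr.shape}")
    if np.any(t_arr < 1) or np.any(t_arr > s.T):
        bad = t_arr[(t_arr < 1) | (t_arr > s.T)][0]
        raise IndexError(f"timestep {bad} out of range; valid timesteps are 1..{s.T}")
    ab = s.alpha_bars[t_arr - 1].reshape(-1, 1, 1, 1)
    return np.sqrt(ab), np.sqrt(1.0 - ab), t_arr


def q_sample(x0, t, eps, s: NoiseSchedule) -> ImageBatch:
    """Corrupt ``x0`` to noise level ``t``: closed-form forward marginal."""
    x0p = _as_pixels(x0, "x0")
    epsp = _as_pixels(eps, "eps")
    _check_shapes(x0p, epsp)
    sab, somab, _ = _step_factors(t, s, x0p.shape[0])
    xt = sab * x0p + somab * epsp
    return ImageBatch(xt.astype(x0p.dtype, copy=False), Domain.NORMALIZED)


def predict_x0(xt, t, eps_hat, s: NoiseSchedule) -> ImageBatch:
    """Invert the forward marginal: recover x0 from (x_t, predicted eps)."""
    xtp = _as_pixels(xt, "xt")
    ehp = _as_pixels(eps_hat, "eps_hat")
    _check_shapes(xtp, ehp)
    sab, somab, _ = _step_factors(t, s, xtp.shape[0])
    x0 = (xtp - somab * ehp) / sab
    return ImageBatch(x0.astype(xtp.dtype, copy=False), Domain.NORMALIZED)


def p_sample_step(xt, t: int, eps_hat, z, s: NoiseSchedule) -> ImageBatch:
    """One ancestral reverse step x_t -> x_{t-1}.

    ``z`` is a standard-Gaussian draw of x_t's shape; it is ignored at t = 1,
    where the reverse step is deterministic.
    """
    xtp = _as_pixels(xt, "xt")
    ehp = _as_pixels(eps_hat, "eps_hat")
    _check_shapes(xtp, ehp)
    c = schedule_constants_at(s, int(t))
    mean = (xtp - (c.beta / c.sqrt_one_minus_alpha_bar) * ehp) / np.sqrt(c.alpha)
    if int(t) > 1:
        zp = _as_pixels(z, "z")
        _check_shapes(xtp, zp)
        mean = mean + c.sigma * zp
    return ImageBatch(mean.astype(xtp.dtype, copy=False), Domain.NORMALIZED)


def noise_prediction_loss(eps_hat, eps, kind=LossKind.HUBER, delta: float = 1.0) -> float:
    """Mean elementwise penalty on the residual r = eps_hat - eps.

    L1: |r|; L2: r^2; Huber: r^2/2 for |r| <= delta, else delta*|r| - delta^2/2.
    """
    kind = LossKind.parse(kind)
    ehp = np.asarray(eps_hat.pixels if isinstance(eps_hat, ImageBatch) else eps_hat)
    epp = np.asarray(eps.pixels if isinstance(eps, ImageBatch) else eps)
    _check_shapes(ehp, epp)
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    r = ehp.astype(np.float64) - epp.astype(np.float64)
    if kind is LossKind.L1:
        return float(np.mean(np.abs(r)))
    if kind is LossKind.L2:
        return float(np.mean(r * r))
    a = np.abs(r)
    quad = 0.5 * r * r
    lin = delta * a - 0.5 * delta * delta
    return float(np.mean(np.where(a <= delta, quad, lin)))
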