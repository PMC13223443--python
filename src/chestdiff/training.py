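"""Training loop, reverse-sampling loop, and run bookkeeping.

One optimizer update draws a uniformly random timestep and a Gaussian noise
field per batch image, corrupts the batch with the closed-form forward
marginal, and regresses the network's noise prediction onto the drawn noise.
Per-epoch mean losses are recorded (the loss-curve history); a checkpoint is
written at the end of the run and optionally per epoch.

Randomness is organized as independent sub-streams derived from one master
seed, one per purpose (data shuffling, timestep draws, noise draws, sampler
noise), so e.g. changing the number of sampled images never perturbs training
reproducibility.
"""

from __future__ import annotations

import csv
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .denoiser import UNetDenoiser, denoise, save_checkpoint
from .diffusion import LossKind, p_sample_step, q_sample
from .images import Domain, ImageBatch, denormalize, normalize
from .nn import Adam
from .schedules import NoiseSchedule

__all__ = [
    "TrainingConfig",
    "TrainingRun",
    "TrainingDivergenceError",
    "derive_rng",
    "train_step",
    "train",
    "sample",
    "write_loss_history",
    "plot_loss_curves",
]

logger = logging.getLogger("chestdiff")


def derive_rng(master_seed: int, purpose: str) -> np.random.Generator:
    """A reproducible sub-stream keyed by (master seed, purpose string)."""
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF,
                                  zlib.crc32(purpose.encode())])


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, loss: float, epoch: int, step: int):
        self.epoch, self.step = epoch, step
        super().__init__(f"non-finite loss {loss} at epoch {epoch}, step {step}")


@dataclass
class TrainingConfig:
    """Hyperparameters of one training run (defaults are paper scale)."""

    epochs: int = 40
    steps_per_epoch: int = 300
    batch_size: int = 32
    learning_rate: float = 1e-3
    loss_kind: LossKind = LossKind.HUBER
    huber_delta: float = 1.0
    seed: int = 0
    drop_last: bool = True
    checkpoint_every_epoch: bool = False

    def __post_init__(self):
        self.loss_kind = LossKind.parse(self.loss_kind)
        for name in ("epochs", "steps_per_epoch", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.learning_rate <= 0 or self.huber_delta <= 0:
            raise ValueError("learning_rate and huber_delta must be positive")


@dataclass
class TrainingRun:
    """Result of :func:`train`: config, loss history, checkpoint reference."""

    config: TrainingConfig
    epoch_losses: list[float]
    checkpoint_path: Path | None
    schedule: NoiseSchedule
    wall_time_s: float = 0.0


def _loss_tensor(eps_hat: Tensor, eps: np.ndarray, kind: LossKind, delta: float) -> Tensor:
    """Differentiable noise-prediction loss (same conventions as
    :func:`chestdiff.diffusion.noise_prediction_loss`)."""
    r = eps_hat - Tensor(eps)
    if kind is LossKind.L1:
        return r.abs().mean()
    if kind is LossKind.L2:
        return (r * r).mean()
    a = np.abs(r.data)
    mask = (a <= delta).astype(r.data.dtype)  # branch choice is not differentiated
    quad = r * r * 0.5
    lin = r.abs() * delta - 0.5 * delta * delta
    return (quad * mask + lin * (1.0 - mask)).mean()


def train_step(
    model: UNetDenoiser,
    x0_batch: ImageBatch,
    s: NoiseSchedule,
    loss_kind: LossKind,
    delta: float,
    rng_t: np.random.Generator,
    rng_eps: np.random.Generator,
    optimizer: Adam,
) -> float:
    """One optimizer update; returns the pre-update loss."""
    x0 = x0_batch.pixels if isinstance(x0_batch, ImageBatch) else np.asarray(x0_batch)
    if isinstance(x0_batch, ImageBatch) and x0_batch.domain is Domain.UINT8:
        raise ValueError("training batches must be NORMALIZED; call normalize() first")
    B = x0.shape[0]
    t = rng_t.integers(1, s.T + 1, size=B)  # uniform on {1..T}
    eps = rng_eps.standard_normal(x0.shape).astype(np.float32)
    xt = q_sample(x0.astype(np.float32, copy=False), t, eps, s)
    optimizer.zero_grad()
    eps_hat = model(Tensor(xt.pixels), t)
    loss = _loss_tensor(eps_hat, eps, LossKind.parse(loss_kind), delta)
    value = float(loss.data)
    loss.backward()
    optimizer.step()
    return value


def _batches(pixels: np.ndarray, batch_size: int, drop_last: bool,
             rng: np.random.Generator):
    """Infinite generator of shuffled batches, reshuffling each pass."""
    n = pixels.shape[0]
    while True:
        order = rng.permutation(n)
        stop = (n // batch_size) * batch_size if drop_last else n
        if stop == 0:
            stop = n  # guarded earlier; keep the generator well-defined
        for i in range(0, stop, batch_size):
            yield pixels[order[i : i + batch_size]]


def train(
    model: UNetDenoiser,
    dataset: ImageBatch,
    config: TrainingConfig,
    s: NoiseSchedule,
    out_dir=None,
) -> TrainingRun:
    """Run ``epochs x steps_per_epoch`` optimizer updates over the dataset.

    ``dataset`` is normalized automatically if given in the UINT8 domain.
    The mean loss of each epoch is recorded; a checkpoint is written under
    ``out_dir`` (when given) at the end of the run, and per epoch when
    ``config.checkpoint_every_epoch`` is set.
    """
    if dataset.domain is Domain.UINT8:
        dataset = normalize(dataset)
    n_batches = len(dataset) // config.batch_size if config.drop_last else \
        -(-len(dataset) // config.batch_size)
    if n_batches < 1:
        raise ValueError(
            f"dataset of {len(dataset)} images yields no full batch of "
            f"{config.batch_size} with drop_last"
        )
    rng_data = derive_rng(config.seed, "data-shuffle")
    rng_t = derive_rng(config.seed, "timestep-draw")
    rng_eps = derive_rng(config.seed, "noise-draw")
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    batches = _batches(dataset.pixels.astype(np.float32, copy=False),
                       config.batch_size, config.drop_last, rng_data)

    out_dir = Path(out_dir) if out_dir is not None else None
    epoch_losses: list[float] = []
    t_start = time.time()
    for epoch in range(1, config.epochs + 1):
        step_losses = np.empty(config.steps_per_epoch)
        t_epoch = time.time()
        for step in range(1, config.steps_per_epoch + 1):
            value = train_step(model, next(batches), s, config.loss_kind,
                               config.huber_delta, rng_t, rng_eps, optimizer)
            if not np.isfinite(value):
                raise TrainingDivergenceError(value, epoch, step)
            step_losses[step - 1] = value
        epoch_losses.append(float(step_losses.mean()))
        logger.info(
            "epoch=%d steps=%d loss=%.6f time_s=%.1f",
            epoch, config.steps_per_epoch, epoch_losses[-1], time.time() - t_epoch,
        )
        if out_dir is not None and config.checkpoint_every_epoch:
            save_checkpoint(out_dir / f"checkpoint_epoch{epoch:04d}.npz", model, s,
                            {"epoch": epoch, "epoch_losses": epoch_losses,
                             "loss_kind": config.loss_kind.name})
    ckpt = None
    if out_dir is not None:
        ckpt = save_checkpoint(out_dir / "checkpoint.npz", model, s,
                               {"epoch": config.epochs, "epoch_losses": epoch_losses,
                                "loss_kind": config.loss_kind.name,
                                "seed": config.seed})
    return TrainingRun(config=config, epoch_losses=epoch_losses,
                       checkpoint_path=ckpt, schedule=s,
                       wall_time_s=time.time() - t_start)


def sample(
    model: UNetDenoiser,
    s: NoiseSchedule,
    n_images: int,
    rng: np.random.Generator | int,
    snapshot_after: set[int] | None = None,
    image_size: int | None = None,
) -> tuple[ImageBatch, list[tuple[int, ImageBatch]]]:
    """Generate images by ancestral reverse diffusion from pure Gaussian noise.

    ``snapshot_after`` holds denoising-step counts (1-based: after k of the T
    reverse steps); a uint8 copy of the batch is recorded at each.  Returns
    the final batch (clamped to [-1, 1], then converted to uint8) and the
    snapshots ordered by step count.
    """
    if n_images < 1:
        raise ValueError("n_images must be positive")
    snapshot_after = set(snapshot_after or ())
    bad = [k for k in snapshot_after if not 1 <= k <= s.T]
    if bad:
        raise ValueError(f"snapshot steps {sorted(bad)} outside 1..T={s.T}")
    if isinstance(rng, (int, np.integer)):
        rng = derive_rng(int(rng), "sampler")
    size = image_size or model.spec.image_size
    x = rng.standard_normal((n_images, 1, size, size)).astype(np.float32)
    snapshots: list[tuple[int, ImageBatch]] = []
    for t in range(s.T, 0, -1):
        eps_hat = denoise(model, x, np.full(n_images, t))
        z = rng.standard_normal(x.shape).astype(np.float32) if t > 1 else None
        x = p_sample_step(x, t, eps_hat, z, s).pixels
        steps_done = s.T - t + 1
        if steps_done in snapshot_after:
            snapshots.append(
                (steps_done, denormalize(ImageBatch(x.copy(), Domain.NORMALIZED)))
            )
    final = denormalize(ImageBatch(x, Domain.NORMALIZED))
    logger.info("sampled n=%d images in T=%d steps, %d snapshots",
                n_images, s.T, len(snapshots))
    return final, snapshots


def write_loss_history(run: TrainingRun, path) -> Path:
    """Write the per-epoch loss history as ``epoch,loss`` CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "loss"])
        for i, loss in enumerate(run.epoch_losses, start=1):
            writer.writerow([i, f"{loss:.8f}"])
    return path


def plot_loss_curves(histories: dict[str, list[float]], path) -> Path:
    """Plot per-epoch loss curves for one or more runs (one line per loss)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, losses in histories.items():
        ax.plot(range(1, len(losses) + 1), losses, label=name)
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
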