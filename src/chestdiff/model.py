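"""Model/Results facade over the diffusion pipeline.

``DiffusionModel`` binds data, a noise schedule, an architecture, and training
hyperparameters; ``fit()`` runs the training loop and returns a
``DiffusionResults`` carrying the loss history, the fitted denoiser, and
generation / evaluation methods.  The underlying building blocks remain
directly usable from :mod:`chestdiff.schedules`, :mod:`chestdiff.diffusion`,
:mod:`chestdiff.denoiser`, :mod:`chestdiff.training` and :mod:`chestdiff.fid`.

Example
-------
>>> from chestdiff import DiffusionModel, generate_phantoms, PhantomParams
>>> data = generate_phantoms(PhantomParams(n=512, seed=7))
>>> model = DiffusionModel(data, T=100, base_channels=8, blocks_per_stage=1,
...                        attention_levels=(2,), num_heads=2,
...                        time_embedding_dim=16, loss_kind="huber")
>>> res = model.fit(epochs=5, steps_per_epoch=50, seed=11)
>>> print(res.summary())          # doctest: +SKIP
>>> imgs, snaps = res.sample(16, seed=3)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .denoiser import DenoiserSpec, UNetDenoiser, build_denoiser, load_checkpoint
from .diffusion import LossKind
from .fid import ProjectionPoolExtractor, fid as _fid
from .images import Domain, ImageBatch, normalize
from .schedules import make_linear_schedule
from .training import (
    TrainingConfig,
    TrainingRun,
    derive_rng,
    plot_loss_curves,
    sample as _sample,
    train,
    write_loss_history,
)

__all__ = ["DiffusionModel", "DiffusionResults"]


class DiffusionModel:
    """A denoising diffusion model bound to an image dataset."""

    def __init__(
        self,
        data: ImageBatch | np.ndarray,
        *,
        T: int = 300,
        beta_start: float = 1e-4,
        beta_end: float = 0.02,
        sigma_variant: str = "beta",
        base_channels: int = 28,
        channel_multipliers: tuple[int, ...] = (1, 2, 4),
        blocks_per_stage: int = 2,
        time_embedding_dim: int = 56,
        attention_levels: tuple[int, ...] = (0, 1, 2),
        num_heads: int = 4,
        loss_kind: str | LossKind = LossKind.HUBER,
        huber_delta: float = 1.0,
    ):
        if not isinstance(data, ImageBatch):
            data = ImageBatch(np.asarray(data), Domain.UINT8
                              if np.asarray(data).dtype == np.uint8 else Domain.NORMALIZED)
        self.data = data if data.domain is Domain.NORMALIZED else normalize(data)
        size = self.data.shape[-1]
        self.schedule = make_linear_schedule(T, beta_start, beta_end,
                                             sigma_variant=sigma_variant)
        self.spec = DenoiserSpec(
            base_channels=base_channels,
            channel_multipliers=tuple(channel_multipliers),
            blocks_per_stage=blocks_per_stage,
            time_embedding_dim=time_embedding_dim,
            attention_levels=tuple(attention_levels),
            num_heads=num_heads,
            image_size=size,
        )
        self.loss_kind = LossKind.parse(loss_kind)
        self.huber_delta = huber_delta

    @classmethod
    def from_config(cls, config, data: ImageBatch) -> "DiffusionModel":
        """Build from a validated :class:`chestdiff.config.RunConfig`."""
        sched, model = config.schedule, dict(config.model)
        model.pop("image_size", None)
        return cls(
            data,
            T=sched["T"], beta_start=sched["beta_start"], beta_end=sched["beta_end"],
            sigma_variant=sched["sigma_variant"],
            loss_kind=config.training["loss_kind"],
            huber_delta=config.training["huber_delta"],
            **model,
        )

    def fit(
        self,
        epochs: int = 40,
        steps_per_epoch: int = 300,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        seed: int = 0,
        out_dir=None,
        checkpoint_every_epoch: bool = False,
    ) -> "DiffusionResults":
        """Train a freshly initialized denoiser; returns the results object."""
        config = TrainingConfig(
            epochs=epochs, steps_per_epoch=steps_per_epoch, batch_size=batch_size,
            learning_rate=learning_rate, loss_kind=self.loss_kind,
            huber_delta=self.huber_delta, seed=seed,
            checkpoint_every_epoch=checkpoint_every_epoch,
        )
        denoiser = build_denoiser(
            self.spec, rng_seed=int(derive_rng(seed, "init").integers(2**31))
        )
        run = train(denoiser, self.data, config, self.schedule, out_dir=out_dir)
        return DiffusionResults(self, denoiser, run)


class DiffusionResults:
    """Fitted diffusion model: loss history, sampling, and evaluation."""

    def __init__(self, model: DiffusionModel | None, denoiser: UNetDenoiser,
                 run: TrainingRun):
        self.model = model
        self.denoiser = denoiser
        self.run = run
        self.schedule = run.schedule

    @property
    def epoch_losses(self) -> list[float]:
        return self.run.epoch_losses

    def summary(self) -> str:
        """Plain-text fitting summary (architecture, schedule, loss history)."""
        cfg = self.run.config
        spec = self.denoiser.spec
        losses = self.epoch_losses
        lines = [
            "Denoising Diffusion Model Results",
            "=" * 46,
            f"{'Denoiser parameters:':<28}{self.denoiser.num_parameters():>18,}",
            f"{'Image size:':<28}{spec.image_size:>18}",
            f"{'Base channels / mults:':<28}{str(spec.base_channels) + ' x ' + str(list(spec.channel_multipliers)):>18}",
            f"{'Diffusion steps T:':<28}{self.schedule.T:>18}",
            f"{'Beta range:':<28}{f'{self.schedule.beta_start:g}..{self.schedule.beta_end:g}':>18}",
            f"{'Loss:':<28}{cfg.loss_kind.name + (f' (delta={cfg.huber_delta:g})' if cfg.loss_kind is LossKind.HUBER else ''):>18}",
            f"{'Epochs x steps:':<28}{f'{cfg.epochs} x {cfg.steps_per_epoch}':>18}",
            f"{'Batch size:':<28}{cfg.batch_size:>18}",
            f"{'Learning rate:':<28}{cfg.learning_rate:>18g}",
            f"{'Seed:':<28}{cfg.seed:>18}",
            "-" * 46,
            f"{'First-epoch mean loss:':<28}{losses[0]:>18.6f}",
            f"{'Final-epoch mean loss:':<28}{losses[-1]:>18.6f}",
            f"{'Wall time (s):':<28}{self.run.wall_time_s:>18.1f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def sample(self, n_images: int, seed: int = 0,
               snapshot_after: set[int] | None = None):
        """Generate images by reverse diffusion; see :func:`chestdiff.training.sample`."""
        return _sample(self.denoiser, self.schedule, n_images,
                       derive_rng(seed, "sampler"), snapshot_after)

    def fid(self, real: ImageBatch, n_generate: int = 256, dim: int = 64,
            seed: int = 0) -> float:
        """Fréchet distance between fresh samples and a real image set."""
        generated, _ = self.sample(n_generate, seed=seed)
        return _fid(real, generated, ProjectionPoolExtractor(dim=dim,
                    image_size=self.denoiser.spec.image_size))

    def plot_loss(self, path) -> Path:
        label = self.run.config.loss_kind.name
        return plot_loss_curves({label: self.epoch_losses}, path)

    def save_loss_history(self, path) -> Path:
        return write_loss_history(self.run, path)

    @staticmethod
    def from_checkpoint(path) -> "DiffusionResults":
        """Rebuild a results object (for sampling) from a checkpoint file."""
        denoiser, schedule, meta = load_checkpoint(path)
        cfg = TrainingConfig(
            epochs=max(1, int(meta.get("epoch", 1))),
            steps_per_epoch=1, batch_size=1,
            loss_kind=meta.get("loss_kind", "huber"),
            seed=int(meta.get("seed", 0)),
        )
        run = TrainingRun(config=cfg, epoch_losses=list(meta.get("epoch_losses", [])),
                          checkpoint_path=Path(path), schedule=schedule)
        return DiffusionResults(None, denoiser, run)
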