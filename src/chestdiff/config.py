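"""Run-configuration loading, validation, and seed management.

A run configuration is a YAML or TOML file with five sections (``schedule``,
``model``, ``training``, ``eval``, ``paths``) plus one master ``seed``.
Absent keys fall back to the defaults below (noise ramp 1e-4 -> 0.02 over
T=300 steps, 40 epochs of 300 updates at batch 32 under the Huber loss,
evaluation at feature dimensions 64 and 2048 on 20,480 generated samples).
Unknown keys are rejected and every violation is reported at once.

Sub-streams of the master seed are derived per purpose; see
:func:`chestdiff.training.derive_rng`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import yaml

from .denoiser import DenoiserSpec
from .schedules import NoiseSchedule, make_linear_schedule
from .training import TrainingConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "DEFAULTS"]

DEFAULTS: dict = {
    "seed": 0,
    "schedule": {"T": 300, "beta_start": 1e-4, "beta_end": 0.02, "sigma_variant": "beta"},
    "model": {
        "base_channels": 28,
        "channel_multipliers": [1, 2, 4],
        "blocks_per_stage": 2,
        "time_embedding_dim": 56,
        "attention_levels": [0, 1, 2],
        "num_heads": 4,
        "image_size": 28,
    },
    "training": {
        "epochs": 40,
        "steps_per_epoch": 300,
        "batch_size": 32,
        "learning_rate": 1e-3,
        "loss_kind": "huber",
        "huber_delta": 1.0,
        "drop_last": True,
        "checkpoint_every_epoch": False,
    },
    "eval": {
        "extractor": "projection-pool",
        "dims": [64, 2048],
        "n_generate": 20480,
        "snapshots": [],
    },
    "paths": {"data": None, "output": "runs"},
}


class ConfigError(ValueError):
    """Raised with the full list of configuration violations."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


@dataclass
class RunConfig:
    """A fully validated run configuration."""

    seed: int
    schedule: dict
    model: dict
    training: dict
    eval: dict
    paths: dict

    def make_schedule(self) -> NoiseSchedule:
        return make_linear_schedule(
            self.schedule["T"], self.schedule["beta_start"],
            self.schedule["beta_end"], sigma_variant=self.schedule["sigma_variant"],
        )

    def make_denoiser_spec(self) -> DenoiserSpec:
        return DenoiserSpec.from_config(self.model)

    def make_training_config(self) -> TrainingConfig:
        return TrainingConfig(seed=self.seed, **self.training)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "schedule": copy.deepcopy(self.schedule),
            "model": copy.deepcopy(self.model),
            "training": copy.deepcopy(self.training),
            "eval": copy.deepcopy(self.eval),
            "paths": copy.deepcopy(self.paths),
        }

    def dump(self, path) -> Path:
        """Echo the resolved configuration beside run outputs."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path


def _parse_file(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        import tomllib

        return tomllib.loads(text)
    data = yaml.safe_load(text)
    return data if data is not None else {}


def _merge(user: dict, problems: list[str]) -> dict:
    merged = copy.deepcopy(DEFAULTS)
    for key, value in user.items():
        if key not in DEFAULTS:
            problems.append(f"unknown top-level key {key!r}")
            continue
        if isinstance(DEFAULTS[key], dict):
            if not isinstance(value, dict):
                problems.append(f"section {key!r} must be a mapping")
                continue
            for sub, subval in value.items():
                if sub not in DEFAULTS[key]:
                    problems.append(f"unknown key {key}.{sub!r}")
                else:
                    merged[key][sub] = subval
        else:
            merged[key] = value
    return merged


def validate(raw: dict) -> RunConfig:
    """Validate a raw (already merged-with-defaults) configuration mapping."""
    problems: list[str] = []
    merged = _merge(raw, problems)

    cfg = RunConfig(
        seed=merged["seed"], schedule=merged["schedule"], model=merged["model"],
        training=merged["training"], eval=merged["eval"], paths=merged["paths"],
    )
    if not isinstance(cfg.seed, int):
        problems.append(f"seed must be an integer, got {cfg.seed!r}")
    try:
        schedule = cfg.make_schedule()
    except (ValueError, TypeError) as exc:
        schedule = None
        problems.append(f"schedule: {exc}")
    try:
        cfg.make_denoiser_spec()
    except (ValueError, TypeError) as exc:
        problems.append(f"model: {exc}")
    try:
        cfg.make_training_config()
    except (ValueError, TypeError) as exc:
        problems.append(f"training: {exc}")
    ev = cfg.eval
    if ev["extractor"] != "projection-pool":
        problems.append(
            f"eval.extractor {ev['extractor']!r} unknown; only 'projection-pool' "
            "is available"
        )
    if not ev["dims"] or any(int(d) < 1 for d in ev["dims"]):
        problems.append(f"eval.dims must be positive integers, got {ev['dims']}")
    if int(ev["n_generate"]) < 2:
        problems.append("eval.n_generate must be >= 2")
    if schedule is not None:
        bad = [k for k in ev["snapshots"] if not 1 <= int(k) <= schedule.T]
        if bad:
            problems.append(f"eval.snapshots {bad} outside 1..T={schedule.T}")
    if problems:
        raise ConfigError(problems)
    return cfg


def load_config(path=None, overrides: list[str] | None = None) -> RunConfig:
    """Load, merge with defaults, apply ``section.key=value`` overrides, validate."""
    raw = _parse_file(Path(path)) if path is not None else {}
    for item in overrides or []:
        if "=" not in item:
            raise ConfigError([f"override {item!r} is not of the form section.key=value"])
        dotted, _, value = item.partition("=")
        parts = dotted.strip().split(".")
        node = raw
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = yaml.safe_load(value)
    return validate(raw)
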