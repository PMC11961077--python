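"""Run configuration: one validated YAML document controls an experiment.

Unknown keys are rejected so typos fail loudly; every field has a default, so
a minimal config only states what deviates from the reference setup.  A single
global seed fans out to per-stage seeds (CRC32 of the stage name mixed with
the global seed) so stages are independently reproducible.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError",
           "stage_seed"]


class ConfigError(ValueError):
    pass


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Section):
    side: int = 64
    n_angles: int = 9
    angle_offset: float = 0.0
    random_offsets: bool = False  # per-slice random start angles


class PhantomSection(_Section):
    n_slices: int = 8
    n_ellipses: int = 6
    smoothness: float = 4.0


class DecoderSection(_Section):
    latent_dim: int = 64
    first_channels: int = 128


class TrainSection(_Section):
    lr_latent: float = 1e-2
    lr_weights: float = 1e-4
    n_iterations: int = 1000
    interpolation_factor: int = 2
    pretrain_lr: float = 1e-3
    pretrain_epochs: int = 50


class TVRegSection(_Section):
    lam: float = 1e-5
    n_iterations: int = 600
    step_scale: float = 0.75
    tv_flavor: str = "anisotropic"


class DIPSection(_Section):
    alpha: float = 1e-6
    n_init_iterations: int = 400
    n_recon_iterations: int = 800
    lr: float = 1e-3
    scales: int = 3
    base_channels: int = 16


class NoiseSection(_Section):
    enabled: bool = False
    n0: float = 1e5
    upsample_factor: float = 3.125


class RunConfig(_Section):
    seed: int = 0
    out_dir: str = "runs/experiment"
    methods: list[str] = ["fbp", "tvreg", "dip", "cglo"]
    geometry: GeometrySection = GeometrySection()
    phantom: PhantomSection = PhantomSection()
    decoder: DecoderSection = DecoderSection()
    train: TrainSection = TrainSection()
    tvreg: TVRegSection = TVRegSection()
    dip: DIPSection = DIPSection()
    noise: NoiseSection = NoiseSection()


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=True))


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed, stable across runs and platforms."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2 ** 31)
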