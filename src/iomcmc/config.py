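"""Experiment configuration and reproducible seed derivation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .imaging import GaussianPRFSpec, NoiseModel
from .mcmc import ChainConfig
from .som_models import GaussianSignalSpec, LumpyModelSpec

__all__ = ["derive_seed", "ExperimentConfig", "load_config", "ConfigError"]


def derive_seed(master_seed: int, *keys: int) -> int:
    """Derive an independent sub-seed from a master seed and integer keys.

    Uses a seed sequence over ``(master_seed, *keys)`` so parallel
    workers need no coordination; the result fits in a signed 32-bit
    integer.
    """
    ss = np.random.SeedSequence((int(master_seed),) + tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


class ConfigError(ValueError):
    """Schema violation in an experiment configuration file."""


def _require(block: dict, key: str, where: str) -> Any:
    if key not in block:
        raise ConfigError(f"missing field '{where}.{key}'")
    return block[key]


@dataclass
class ExperimentConfig:
    """Validated experiment description: task + observer + study blocks."""

    task_kind: str
    lumpy: Optional[LumpyModelSpec]
    prf: Optional[GaussianPRFSpec]
    signal: Optional[GaussianSignalSpec]
    noise: NoiseModel
    generator_kind: Optional[str]
    generator_options: dict
    observer_engine: str
    chain: ChainConfig
    n_per_class: int
    master_seed: int
    output_dir: Path
    n_cov_samples: int = 50_000
    raw: dict = field(default_factory=dict)


_ENGINES = {"hotelling", "mcmc", "analytic-io", "oracle-quadrature", "oracle-prior-mc"}
_TASK_KINDS = {"lumpy", "linear-gaussian", "blob"}


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration.

    Any missing or malformed field raises :class:`ConfigError` naming the
    offending field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    task = _require(raw, "task", "")
    kind = _require(task, "kind", "task")
    if kind not in _TASK_KINDS:
        raise ConfigError(f"task.kind must be one of {sorted(_TASK_KINDS)}")

    noise_blk = _require(task, "noise", "task")
    try:
        noise = NoiseModel(
            kind=noise_blk.get("kind", "real"),
            sigma=float(_require(noise_blk, "sigma", "task.noise")),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"task.noise: {exc}") from exc

    lumpy = prf = signal = None
    generator_kind = None
    generator_options: dict = {}
    if kind == "lumpy":
        try:
            lumpy = LumpyModelSpec(**task.get("lumpy", {}))
            prf = GaussianPRFSpec(**task.get("prf", {}))
            sig = dict(task.get("signal", {}))
            if "center" in sig:
                sig["center"] = tuple(sig["center"])
            signal = GaussianSignalSpec(**sig)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"task block: {exc}") from exc
    else:
        generator_kind = kind
        generator_options = dict(task.get("generator", {}))
        if "signal" in task:
            sig = dict(task["signal"])
            if "center" in sig:
                sig["center"] = tuple(sig["center"])
            try:
                signal = GaussianSignalSpec(**sig)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"task.signal: {exc}") from exc

    obs = _require(raw, "observer", "")
    engine = _require(obs, "engine", "observer")
    if engine not in _ENGINES:
        raise ConfigError(f"observer.engine must be one of {sorted(_ENGINES)}")
    try:
        chain = ChainConfig(**obs.get("chain", {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"observer.chain: {exc}") from exc

    study = _require(raw, "study", "")
    try:
        n_per_class = int(_require(study, "n_per_class", "study"))
        master_seed = int(_require(study, "master_seed", "study"))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"study block: {exc}") from exc
    if n_per_class <= 0:
        raise ConfigError("study.n_per_class must be positive")
    output_dir = Path(study.get("output_dir", "results"))

    return ExperimentConfig(
        task_kind=kind,
        lumpy=lumpy,
        prf=prf,
        signal=signal,
        noise=noise,
        generator_kind=generator_kind,
        generator_options=generator_options,
        observer_engine=engine,
        chain=chain,
        n_per_class=n_per_class,
        master_seed=master_seed,
        output_dir=output_dir,
        n_cov_samples=int(study.get("n_cov_samples", 50_000)),
        raw=raw,
    )
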