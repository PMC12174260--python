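"""Simulation configuration: defaults, validation and YAML loading.

A :class:`SimulationConfig` collects everything a run needs — circuit count,
sample count, sampling rate, the position encoder, homogeneous SyS/DT
defaults with per-synapse overrides, the motor plant, optional plasticity
and the desired-position trajectory — and can materialise the concrete
objects the simulator consumes.  Configs round-trip through plain dicts (and
hence YAML / JSON run manifests).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cmc_core import CIRCUIT_NEURONS, CIRCUIT_SYNAPSES, SynapticParams
from .motor_plant import (
    MotorConfig,
    constant_trajectory,
    sinusoid_trajectory,
    step_trajectory,
)
from .plasticity import PlasticityConfig
from .rate_coding import RateCodingConfig

__all__ = ["SimulationConfig", "load_config"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Fully-specified simulation run (circuit + plant + task)."""

    n_cmc: int = 100_000
    n_samples: int = 2500
    seed: int = 0
    sampling_frequency_hz: float = 250.0
    encoder_low: float = 0.0
    encoder_high: float = 1.0
    sys_default: float = 1.5
    dt_default: float = 0.15
    sys_overrides: dict[str, float] = field(default_factory=dict)
    dt_overrides: dict[str, float] = field(default_factory=dict)
    trajectory: dict = field(default_factory=lambda: {"kind": "sinusoid", "freq_hz": 0.1})
    motor: MotorConfig = field(default_factory=MotorConfig)
    adaptive: bool = False
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)

    def __post_init__(self) -> None:
        if self.n_cmc < 1:
            raise ValueError("n_cmc must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        unknown = (set(self.sys_overrides) - set(CIRCUIT_SYNAPSES)) | (
            set(self.dt_overrides) - set(CIRCUIT_NEURONS)
        )
        if unknown:
            raise ValueError(f"unknown synapse/neuron overrides: {sorted(unknown)}")
        self.rate_config()  # validates sampling rate and encoder range

    # -- effective parameter helpers (overrides win over defaults) ---------

    def effective_sys(self, name: str) -> float:
        return self.sys_overrides.get(name, self.sys_default)

    def effective_dt(self, name: str) -> float:
        return self.dt_overrides.get(name, self.dt_default)

    # -- materialisation ---------------------------------------------------

    def rate_config(self) -> RateCodingConfig:
        return RateCodingConfig(
            sampling_frequency=self.sampling_frequency_hz,
            encoder_low=self.encoder_low,
            encoder_high=self.encoder_high,
        )

    def build_params(self, n: int | None = None) -> SynapticParams:
        return SynapticParams.homogeneous(
            n if n is not None else self.n_cmc,
            sys_default=self.sys_default,
            dt_default=self.dt_default,
            sys_overrides=self.sys_overrides,
            dt_overrides=self.dt_overrides,
        )

    def build_trajectory(self) -> np.ndarray:
        spec = dict(self.trajectory)
        kind = spec.pop("kind", "sinusoid")
        if kind == "sinusoid":
            return sinusoid_trajectory(
                self.n_samples, sampling_hz=self.sampling_frequency_hz, **spec
            )
        if kind == "constant":
            return constant_trajectory(self.n_samples, **spec)
        if kind == "step":
            traj = step_trajectory(**spec)
            return traj[: self.n_samples]
        raise ValueError(f"unknown trajectory kind: {kind!r}")

    def rng(self, seed: int | None = None) -> np.random.Generator:
        return np.random.default_rng(self.seed if seed is None else seed)

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        for key in list(data):
            if key not in known:
                log.warning("ignoring unknown config key: %s", key)
                data.pop(key)
        if "motor" in data and isinstance(data["motor"], dict):
            data["motor"] = MotorConfig(**data["motor"])
        if "plasticity" in data and isinstance(data["plasticity"], dict):
            data["plasticity"] = PlasticityConfig(**data["plasticity"])
        return cls(**data)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML config file; absent keys fall back to the defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return SimulationConfig.from_dict(data)
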