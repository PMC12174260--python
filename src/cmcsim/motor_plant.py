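"""Comparator network and idealised joint for closed-loop position following.

The plant follows the cerebellar-brain-inhibition picture: per CmC, the DCN
output is compared against the motor signal (identified with the climbing
fibre state) through a small Boolean network (P1, P2, P3, flexor,
extensor-interneuron, extensor) using the same stochastic threshold rule as
the circuit itself.  The population flexor/extensor balance, scaled by muscle
strength, moves an idealised joint whose position lives in [0, 1] (0 = full
extension, 1 = full flexion).

Sign conventions: the flexor pushes position up, the extensor down; a
"gravitational" external force is a negative ``force_on_joint`` (towards
extension), an "anti-gravitational" force positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmc_core import CmCState, SynapticParams, step_cmc_population
from .rate_coding import RateCodingConfig, encode_position, sample_afferent

__all__ = [
    "COMPARATOR_SYNAPSES",
    "COMPARATOR_NEURONS",
    "MotorConfig",
    "ComparatorState",
    "comparator_equation",
    "step_comparator",
    "muscle_power",
    "simple_muscle_power",
    "update_joint",
    "movement_error",
    "run_closed_loop",
    "sinusoid_trajectory",
    "constant_trajectory",
    "step_trajectory",
]

#: Comparator synapses in RNG consumption order within a sample.
COMPARATOR_SYNAPSES = (
    "dcn_p1",
    "motor_p1",
    "motor_p2",
    "dcn_p2",
    "p1_p3",
    "p2_p3",
    "p3_flexor",
    "dcn_flexor",
    "p3_extint",
    "dcn_extint",
    "p3_extensor",
    "extint_extensor",
)

COMPARATOR_NEURONS = ("p1", "p2", "p3", "flexor", "extensor_interneuron", "extensor")


def _default_sys() -> dict[str, float]:
    return {s: 1.5 for s in COMPARATOR_SYNAPSES}


def _default_dt() -> dict[str, float]:
    return {m: 0.15 for m in COMPARATOR_NEURONS}


@dataclass
class MotorConfig:
    """Muscle / joint parameters and the comparator-network SyS / DT values.

    ``muscle_strength`` is the maximum muscle force, expressed as joint
    velocity (position-units per second); ``power_scale`` converts it to a
    per-sample displacement and defaults to the 4 ms sampling step of the
    250 Hz model (set it to ``1/sampling`` if you change the rate, or to 1 to
    read power directly in position-units per sample).  ``force_on_joint`` is
    an external force added to the scaled power, in position-units per
    sample; negative pushes towards extension.
    """

    muscle_strength: float = 10.0
    force_on_joint: float = 0.0
    flexor_excitability: float = 1.0
    extensor_excitability: float = 1.0
    power_scale: float = 1.0 / 250.0
    sys: dict[str, float] = field(default_factory=_default_sys)
    dt: dict[str, float] = field(default_factory=_default_dt)

    def __post_init__(self) -> None:
        if self.muscle_strength < 0:
            raise ValueError("muscle_strength must be >= 0")
        if self.flexor_excitability < 0 or self.extensor_excitability < 0:
            raise ValueError("excitability gains must be >= 0")
        missing = (set(COMPARATOR_SYNAPSES) - set(self.sys)) | (
            set(COMPARATOR_NEURONS) - set(self.dt)
        )
        if missing:
            raise ValueError(f"missing comparator parameters: {sorted(missing)}")

    def copy(self) -> "MotorConfig":
        return MotorConfig(
            muscle_strength=self.muscle_strength,
            force_on_joint=self.force_on_joint,
            flexor_excitability=self.flexor_excitability,
            extensor_excitability=self.extensor_excitability,
            power_scale=self.power_scale,
            sys=dict(self.sys),
            dt=dict(self.dt),
        )


@dataclass
class ComparatorState:
    """Boolean state of the comparator network at one sample."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    flexor: np.ndarray
    extensor_interneuron: np.ndarray
    extensor: np.ndarray


def comparator_equation(
    terms: list[tuple[np.ndarray, float]],
    dt: float,
    rng: np.random.Generator,
    gain: float = 1.0,
) -> np.ndarray:
    """One comparator equation: ``X * gain * sum_i w_i * state_i > dt``.

    ``terms`` pairs each Boolean input vector with its signed weight
    (negative = inhibitory).  A *single* uniform draw multiplies the whole
    signed weight sum, so equal excitation and inhibition cancel exactly —
    this is what makes the combined DCN + motor state produce no movement
    and keeps the flexor and extensor from co-activating.  Draws are
    consumed only where at least one input is active.
    """
    first = np.asarray(terms[0][0])
    net = np.zeros(first.shape[0], dtype=float)
    active = np.zeros(first.shape[0], dtype=bool)
    for vec, weight in terms:
        vec = np.asarray(vec)
        net += weight * vec.astype(float)
        active |= vec != 0
    out = np.zeros(first.shape[0], dtype=np.uint8)
    idx = np.flatnonzero(active)
    if idx.size:
        x = rng.random(idx.size)
        out[idx] = (x * gain * net[idx] > dt).astype(np.uint8)
    return out


def step_comparator(
    dcn: np.ndarray,
    motor_signal: np.ndarray,
    cfg: MotorConfig,
    rng: np.random.Generator,
) -> ComparatorState:
    """Evaluate the comparator network for one sample.

    P1 fires when the DCN beats the motor signal, P2 when the motor signal
    beats the DCN; P3 pools them; the flexor and the extensor-interneuron are
    both driven by P3 and inhibited by the DCN; the extensor is driven by P3
    and inhibited by the extensor-interneuron.  Excitability gains multiply
    the flexor/extensor drive before thresholding.  Each equation uses one
    shared uniform draw across its terms (see :func:`comparator_equation`).
    """
    dcn = np.asarray(dcn)
    motor_signal = np.asarray(motor_signal)
    if dcn.shape != motor_signal.shape:
        raise ValueError("dcn and motor_signal must have the same length")
    s, d = cfg.sys, cfg.dt

    p1 = comparator_equation(
        [(dcn, s["dcn_p1"]), (motor_signal, -s["motor_p1"])], d["p1"], rng
    )
    p2 = comparator_equation(
        [(motor_signal, s["motor_p2"]), (dcn, -s["dcn_p2"])], d["p2"], rng
    )
    p3 = comparator_equation([(p1, s["p1_p3"]), (p2, s["p2_p3"])], d["p3"], rng)
    flexor = comparator_equation(
        [(p3, s["p3_flexor"]), (dcn, -s["dcn_flexor"])],
        d["flexor"], rng, gain=cfg.flexor_excitability,
    )
    ext_int = comparator_equation(
        [(p3, s["p3_extint"]), (dcn, -s["dcn_extint"])],
        d["extensor_interneuron"], rng,
    )
    extensor = comparator_equation(
        [(p3, s["p3_extensor"]), (ext_int, -s["extint_extensor"])],
        d["extensor"], rng, gain=cfg.extensor_excitability,
    )
    return ComparatorState(p1, p2, p3, flexor, ext_int, extensor)


def muscle_power(
    flexor: np.ndarray, extensor: np.ndarray, cfg: MotorConfig, force: float | None = None
) -> float:
    """Population muscle power: mean(flexor - extensor) scaled by strength.

    ``force`` overrides ``cfg.force_on_joint`` when given (used for
    time-varying force schedules).
    """
    flexor = np.asarray(flexor)
    extensor = np.asarray(extensor)
    if flexor.size == 0:
        raise ValueError("need at least one CmC")
    f = cfg.force_on_joint if force is None else force
    balance = float(np.mean(flexor.astype(float) - extensor.astype(float)))
    return balance * cfg.muscle_strength * cfg.power_scale + f


def simple_muscle_power(
    motor_signal: np.ndarray, dcn: np.ndarray, cfg: MotorConfig
) -> float:
    """Diagnostic power from the raw motor-signal / DCN difference (no comparator)."""
    motor_signal = np.asarray(motor_signal)
    dcn = np.asarray(dcn)
    if motor_signal.size == 0:
        raise ValueError("need at least one CmC")
    balance = float(np.mean(motor_signal.astype(float) - dcn.astype(float)))
    return balance * cfg.muscle_strength * cfg.power_scale


def update_joint(position: float, power: float) -> float:
    """Advance the joint by one sample; position is clamped to [0, 1]."""
    return float(np.clip(position + power, 0.0, 1.0))


def movement_error(actual: float, desired: float) -> float:
    """Absolute difference between achieved and desired joint position."""
    return abs(actual - desired)


# --------------------------------------------------------------------------
# desired-position trajectory generators


def sinusoid_trajectory(
    n_samples: int,
    sampling_hz: float = 250.0,
    freq_hz: float = 0.1,
    amplitude: float = 0.5,
    offset: float = 0.5,
    phase: float = 0.0,
) -> np.ndarray:
    """Sinusoidal desired position spanning [offset-amplitude, offset+amplitude]."""
    t = np.arange(n_samples) / sampling_hz
    traj = offset + amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    return np.clip(traj, 0.0, 1.0)


def constant_trajectory(n_samples: int, level: float = 0.5) -> np.ndarray:
    return np.full(n_samples, float(level))


def step_trajectory(levels: list[float], samples_per_level: int) -> np.ndarray:
    return np.repeat(np.asarray(levels, dtype=float), samples_per_level)


# --------------------------------------------------------------------------
# closed loop


def run_closed_loop(
    desired: np.ndarray,
    params: SynapticParams,
    motor_cfg: MotorConfig,
    rate_cfg: RateCodingConfig,
    rng: np.random.Generator,
    *,
    plasticity=None,
    force_schedule: np.ndarray | None = None,
    initial_position: float | None = None,
    record_rates: bool = False,
) -> pd.DataFrame:
    """Run the full feedback loop over a desired-position trajectory.

    Per sample: the actual joint position is encoded as the mossy-fibre
    probability and the desired position as the climbing-fibre probability;
    afferents are sampled, the circuit and comparator networks are stepped,
    the population muscle power moves the joint and the error is recorded.
    If ``plasticity`` is given, its ``update(state, params)`` hook runs after
    every circuit step.  ``force_schedule`` (position-units per sample)
    overrides the constant ``motor_cfg.force_on_joint`` per sample.

    Returns a DataFrame with columns ``t, desired, actual, muscle_power,
    error, mean_dcn`` (plus per-neuron mean rates if ``record_rates``).
    """
    desired = np.asarray(desired, dtype=float)
    if desired.ndim != 1 or desired.size == 0:
        raise ValueError("desired trajectory must be a non-empty 1-D array")
    if np.any(desired < 0) or np.any(desired > 1):
        raise ValueError("desired positions must lie in [0, 1]")
    if force_schedule is not None:
        force_schedule = np.asarray(force_schedule, dtype=float)
        if force_schedule.shape != desired.shape:
            raise ValueError("force_schedule must match the trajectory length")

    n = params.n
    n_samples = desired.size
    state = CmCState.zeros(n)
    position = float(desired[0]) if initial_position is None else float(initial_position)

    cols: dict[str, np.ndarray] = {
        "t": np.arange(n_samples, dtype=float),
        "desired": desired.copy(),
        "actual": np.empty(n_samples),
        "muscle_power": np.empty(n_samples),
        "error": np.empty(n_samples),
        "mean_dcn": np.empty(n_samples),
    }
    if record_rates:
        for name in ("granule", "golgi", "ii", "purkinje", "flexor", "extensor"):
            cols[f"mean_{name}"] = np.empty(n_samples)

    for t in range(n_samples):
        mossy_p = encode_position(position, rate_cfg)
        climbing_p = encode_position(float(desired[t]), rate_cfg)
        mossy = sample_afferent(mossy_p, n, rng)
        climbing = sample_afferent(climbing_p, n, rng)
        state = step_cmc_population(mossy, climbing, state, params, rng)
        if plasticity is not None:
            plasticity.update(state, params)
        comp = step_comparator(state.dcn, climbing, motor_cfg, rng)
        force = None if force_schedule is None else float(force_schedule[t])
        power = muscle_power(comp.flexor, comp.extensor, motor_cfg, force=force)

        cols["actual"][t] = position
        cols["muscle_power"][t] = power
        cols["error"][t] = movement_error(position, float(desired[t]))
        cols["mean_dcn"][t] = float(state.dcn.mean())
        if record_rates:
            cols["mean_granule"][t] = float(state.granule.mean())
            cols["mean_golgi"][t] = float(state.golgi.mean())
            cols["mean_ii"][t] = float(state.inhibitory_interneuron.mean())
            cols["mean_purkinje"][t] = float(state.purkinje.mean())
            cols["mean_flexor"][t] = float(comp.flexor.mean())
            cols["mean_extensor"][t] = float(comp.extensor.mean())

        position = update_joint(position, power)

    return pd.DataFrame(cols)
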