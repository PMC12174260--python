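"""Temporal-summation variant of the circuit (500 Hz sampling).

Each neuron keeps a carried "neurotransmitter effect" in [-1, 1].  Per
sample, the neuron fires iff the carried effect plus the current signed
synaptic drive exceeds its DT *and* the carried effect is non-negative; on
firing the effect is set to -1 (absolute refractory lockout until it decays
back to 0), otherwise the subthreshold drive is accumulated.  Either way the
effect is then scaled by a linear decay factor

    decay = (refractory_ms - step_ms) / refractory_ms

so with the default 3 ms refractory period and 2 ms step the decay factor is
1/3, and a fired neuron is locked out for exactly one intervening sample
(4 ms between spikes > 3 ms refractory).  With decay 0 the engine is
memoryless and statistically identical to the non-temporal model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cmc_core import SynapticParams, masked_drive
from .rate_coding import sample_afferent, sampling_step_ms

__all__ = [
    "TemporalConfig",
    "MembraneState",
    "decay_factor",
    "step_temporal_neuron",
    "run_temporal_cmc",
]

_TEMPORAL_NEURONS = ("granule", "golgi", "ii", "purkinje", "dcn")


def decay_factor(refractory_ms: float, step_ms: float) -> float:
    """Fraction of the carried effect surviving to the next sample."""
    if step_ms <= 0:
        raise ValueError("sampling step must be > 0")
    if step_ms > refractory_ms:
        raise ValueError(
            f"sampling step ({step_ms} ms) must not exceed the refractory "
            f"period ({refractory_ms} ms); the temporal model would degenerate"
        )
    return (refractory_ms - step_ms) / refractory_ms


@dataclass(frozen=True)
class TemporalConfig:
    """Sampling rate and refractory period of the temporal engine."""

    sampling_frequency: float = 500.0
    refractory_ms: float = 3.0
    decay_override: float | None = None  # set to force a decay factor

    @property
    def step_ms(self) -> float:
        return sampling_step_ms(self.sampling_frequency)

    @property
    def decay(self) -> float:
        if self.decay_override is not None:
            if not (0.0 <= self.decay_override < 1.0):
                raise ValueError("decay override must lie in [0, 1)")
            return self.decay_override
        return decay_factor(self.refractory_ms, self.step_ms)


class MembraneState:
    """Carried neurotransmitter effect per neuron type across n CmCs."""

    def __init__(self, n: int):
        self.effect = {name: np.zeros(n) for name in _TEMPORAL_NEURONS}

    def bounded(self) -> bool:
        return all(
            np.all(v >= -1.0) and np.all(v <= 1.0) for v in self.effect.values()
        )


def step_temporal_neuron(
    drive: np.ndarray, carried: np.ndarray, dt: np.ndarray | float, decay: float
) -> tuple[np.ndarray, np.ndarray]:
    """Advance one neuron type by one sample.

    Returns ``(fired, new_effect)``.  Firing requires the summed potential to
    beat DT while the membrane is not refractory (carried >= 0).
    """
    drive = np.asarray(drive, dtype=float)
    carried = np.asarray(carried, dtype=float)
    potential = carried + drive
    fired = ((potential > dt) & (carried >= 0.0)).astype(np.uint8)
    new_effect = np.where(
        fired == 1, -1.0, np.clip(potential, -1.0, 1.0)
    ) * decay
    return fired, new_effect


def run_temporal_cmc(
    mossy_probs: np.ndarray,
    climbing_probs: np.ndarray,
    params: SynapticParams,
    cfg: TemporalConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Run the temporal circuit over afferent probability series.

    ``mossy_probs`` / ``climbing_probs`` give the per-sample afferent firing
    probabilities.  Returns a raster per neuron type: Boolean arrays of shape
    (n_samples, n), keys ``mossy_fibre, climbing_fibre, granule, golgi, ii,
    purkinje, dcn``.
    """
    mossy_probs = np.atleast_1d(np.asarray(mossy_probs, dtype=float))
    climbing_probs = np.atleast_1d(np.asarray(climbing_probs, dtype=float))
    if mossy_probs.shape != climbing_probs.shape:
        raise ValueError("afferent probability series must have equal length")
    n = params.n
    n_samples = mossy_probs.size
    decay = cfg.decay
    mem = MembraneState(n)
    golgi_prev = np.zeros(n, dtype=np.uint8)

    raster = {
        name: np.zeros((n_samples, n), dtype=np.uint8)
        for name in ("mossy_fibre", "climbing_fibre", *_TEMPORAL_NEURONS)
    }

    for t in range(n_samples):
        mossy = sample_afferent(float(mossy_probs[t]), n, rng)
        climbing = sample_afferent(float(climbing_probs[t]), n, rng)

        drive = masked_drive(mossy, params.sys["mf_granule"], rng)
        drive -= masked_drive(golgi_prev, params.sys["golgi_granule"], rng)
        granule, mem.effect["granule"] = step_temporal_neuron(
            drive, mem.effect["granule"], params.dt["granule"], decay
        )

        drive = masked_drive(granule, params.sys["granule_golgi"], rng)
        golgi, mem.effect["golgi"] = step_temporal_neuron(
            drive, mem.effect["golgi"], params.dt["golgi"], decay
        )

        drive = masked_drive(granule, params.sys["granule_ii"], rng)
        ii, mem.effect["ii"] = step_temporal_neuron(
            drive, mem.effect["ii"], params.dt["ii"], decay
        )

        drive = masked_drive(granule, params.sys["granule_purkinje"], rng)
        drive += masked_drive(climbing, params.sys["cf_purkinje"], rng)
        drive -= masked_drive(ii, params.sys["ii_purkinje"], rng)
        purkinje, mem.effect["purkinje"] = step_temporal_neuron(
            drive, mem.effect["purkinje"], params.dt["purkinje"], decay
        )

        drive = masked_drive(mossy, params.sys["mf_dcn"], rng)
        drive += masked_drive(climbing, params.sys["cf_dcn"], rng)
        drive -= masked_drive(purkinje, params.sys["purkinje_dcn"], rng)
        dcn, mem.effect["dcn"] = step_temporal_neuron(
            drive, mem.effect["dcn"], params.dt["dcn"], decay
        )

        raster["mossy_fibre"][t] = mossy
        raster["climbing_fibre"][t] = climbing
        raster["granule"][t] = granule
        raster["golgi"][t] = golgi
        raster["ii"][t] = ii
        raster["purkinje"][t] = purkinje
        raster["dcn"][t] = dcn
        golgi_prev = golgi

    return raster
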