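"""Activity-dependent LTP/LTD rules on the circuit's synaptic strengths.

Six rules modify five synapses, per CmC and per sample:

==========================  =========  =====================================
target synapse              direction  trigger
==========================  =========  =====================================
granule -> Purkinje         LTD        granule & climbing fire same sample
granule -> Purkinje         LTP        granule activity high, climbing not
mossy -> granule            LTP        mossy activity high
climbing -> Purkinje        LTP        climbing activity high
mossy -> DCN                LTD        mossy activity low
Purkinje -> DCN             LTD        DCN fires while Purkinje activity low
==========================  =========  =====================================

"Activity" is an exponential moving average (EMA) of the Boolean firing
state, classified as low / mid / high against two probability cutoffs.  A
triggered rule multiplies its synapse's SyS by (1 +/- step_fraction); a
synapse whose rules did not trigger relaxes geometrically back to its
baseline.  SyS is clipped to [sys_min, sys_max] throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cmc_core import CmCState, SynapticParams

__all__ = [
    "PLASTIC_SYNAPSES",
    "PlasticityConfig",
    "PlasticityState",
    "classify_activity",
    "relax_to_baseline",
]

PLASTIC_SYNAPSES = (
    "mf_granule",
    "granule_purkinje",
    "cf_purkinje",
    "mf_dcn",
    "purkinje_dcn",
)


@dataclass(frozen=True)
class PlasticityConfig:
    """Thresholds, step sizes and timescales of the plasticity rules.

    All are per-sample quantities; the defaults are slow relative to 250 Hz
    sampling so adaptation unfolds over a few hundred samples.
    """

    high_threshold: float = 0.6
    low_threshold: float = 0.2
    step_fraction: float = 0.01
    relax_rate: float = 0.001
    ema_alpha: float = 0.01
    sys_min: float = 0.1
    sys_max: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_threshold < self.high_threshold <= 1.0):
            raise ValueError("require 0 <= low_threshold < high_threshold <= 1")
        if not (0.0 < self.step_fraction < 1.0):
            raise ValueError("step_fraction must be in (0, 1)")
        if not (0.0 < self.relax_rate <= 1.0):
            raise ValueError("relax_rate must be in (0, 1]")
        if not (0.0 < self.ema_alpha <= 1.0):
            raise ValueError("ema_alpha must be in (0, 1]")
        if self.sys_min < 0 or self.sys_max < self.sys_min:
            raise ValueError("require 0 <= sys_min <= sys_max")


def classify_activity(ema: float, cfg: PlasticityConfig) -> str:
    """Classify an activity estimate as 'low', 'mid' or 'high'."""
    if not (0.0 <= ema <= 1.0):
        raise ValueError("activity estimate must lie in [0, 1]")
    if ema <= cfg.low_threshold:
        return "low"
    if ema >= cfg.high_threshold:
        return "high"
    return "mid"


def relax_to_baseline(
    sys: np.ndarray | float, baseline: np.ndarray | float, relax_rate: float
) -> np.ndarray | float:
    """One geometric relaxation step of SyS toward its baseline value."""
    if not (0.0 < relax_rate <= 1.0):
        raise ValueError("relax_rate must be in (0, 1]")
    return sys + relax_rate * (np.asarray(baseline) - sys)


class PlasticityState:
    """Baseline snapshot, per-CmC activity EMAs and the rule engine.

    ``update(state, params)`` mutates ``params.sys`` in place once per
    sample; pass an instance as the ``plasticity`` hook of
    :func:`cmcsim.motor_plant.run_closed_loop`.
    """

    def __init__(self, params: SynapticParams, cfg: PlasticityConfig | None = None):
        self.cfg = cfg or PlasticityConfig()
        self.baseline = {s: params.sys[s].copy() for s in PLASTIC_SYNAPSES}
        n = params.n
        self.ema = {
            name: np.zeros(n) for name in ("mossy", "climbing", "granule", "purkinje")
        }

    def update(self, state: CmCState, params: SynapticParams) -> None:
        cfg = self.cfg
        a = cfg.ema_alpha
        self.ema["mossy"] += a * (state.mossy_fibre - self.ema["mossy"])
        self.ema["climbing"] += a * (state.climbing_fibre - self.ema["climbing"])
        self.ema["granule"] += a * (state.granule - self.ema["granule"])
        self.ema["purkinje"] += a * (state.purkinje - self.ema["purkinje"])

        mossy_high = self.ema["mossy"] >= cfg.high_threshold
        mossy_low = self.ema["mossy"] <= cfg.low_threshold
        climbing_high = self.ema["climbing"] >= cfg.high_threshold
        granule_high = self.ema["granule"] >= cfg.high_threshold
        purkinje_low = self.ema["purkinje"] <= cfg.low_threshold

        coactive = (state.granule == 1) & (state.climbing_fibre == 1)
        triggers: dict[str, list[tuple[np.ndarray, float]]] = {
            "granule_purkinje": [
                (coactive, 1.0 - cfg.step_fraction),  # PF+CF co-activation LTD
                (granule_high & ~climbing_high, 1.0 + cfg.step_fraction),  # isolated PF LTP
            ],
            "mf_granule": [(mossy_high, 1.0 + cfg.step_fraction)],
            "cf_purkinje": [(climbing_high, 1.0 + cfg.step_fraction)],
            "mf_dcn": [(mossy_low, 1.0 - cfg.step_fraction)],
            "purkinje_dcn": [
                ((state.dcn == 1) & purkinje_low, 1.0 - cfg.step_fraction)
            ],
        }

        for synapse, rules in triggers.items():
            sys = params.sys[synapse]
            any_triggered = np.zeros(sys.shape, dtype=bool)
            for mask, factor in rules:
                sys[mask] *= factor
                any_triggered |= mask
            idle = ~any_triggered
            base = self.baseline[synapse]
            sys[idle] += cfg.relax_rate * (base[idle] - sys[idle])
            np.clip(sys, cfg.sys_min, cfg.sys_max, out=sys)

    def mean_sys(self, params: SynapticParams) -> dict[str, float]:
        """Population-mean SyS of each plastic synapse (for inspection CSVs)."""
        return {s: float(params.sys[s].mean()) for s in PLASTIC_SYNAPSES}
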