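"""Pathology and intervention presets.

Each preset is a pure transform of a :class:`~cmcsim.config.SimulationConfig`
into a perturbed copy: identical inputs give identical outputs and identity
arguments give back an equivalent config.

Presets:

* ``preset_neocerebellar`` — loss of micro complexes (circuit-count cut),
  producing intention tremor.
* ``preset_ethanol`` — acute alcohol intoxication: GABAergic SyS scaled up,
  glutamatergic SyS scaled down to a lesser extent.
* ``preset_kcna1`` — Kv1.1 loss of function (episodic ataxia type 1):
  hyperexcitable inhibitory interneurons via a lowered DT.
* ``preset_cacna1a`` — CaV2.1 channelopathies: ``tottering`` cuts
  neurotransmitter release of the affected synapses by 65% (SyS x 0.35),
  ``rocker`` by 85% (SyS x 0.15).
* ``preset_dcn_bias`` — tonic (dis)inhibition of the DCN via a DT shift,
  the hypothesised compensation for a constant external force.
"""

from __future__ import annotations

from .cmc_core import GABAERGIC_SYNAPSES, GLUTAMATERGIC_SYNAPSES
from .config import SimulationConfig

__all__ = [
    "CACNA1A_FACTORS",
    "CACNA1A_SYNAPSES",
    "preset_neocerebellar",
    "preset_ethanol",
    "preset_kcna1",
    "preset_cacna1a",
    "preset_dcn_bias",
]

#: SyS multipliers implied by the reported neurotransmitter-release cuts.
CACNA1A_FACTORS = {"tottering": 1.0 - 0.65, "rocker": 1.0 - 0.85}

#: CaV2.1-dependent synapses: granule-cell efferents, climbing-fibre
#: efferents and the Purkinje->DCN terminal.
CACNA1A_SYNAPSES = (
    "granule_golgi",
    "granule_ii",
    "granule_purkinje",
    "cf_purkinje",
    "cf_dcn",
    "purkinje_dcn",
)


def _scale_sys(cfg: SimulationConfig, names, factor: float) -> SimulationConfig:
    if factor == 1.0:
        return cfg
    overrides = dict(cfg.sys_overrides)
    for name in names:
        overrides[name] = cfg.effective_sys(name) * factor
    return cfg.replace(sys_overrides=overrides)


def preset_neocerebellar(cfg: SimulationConfig, n_cmc: int) -> SimulationConfig:
    """Reduce the number of functioning micro complexes."""
    if n_cmc < 1:
        raise ValueError("n_cmc must be >= 1")
    return cfg.replace(n_cmc=int(n_cmc))


def preset_ethanol(
    cfg: SimulationConfig, gaba_factor: float = 1.5, glu_factor: float = 0.8
) -> SimulationConfig:
    """Scale GABAergic synapses up and glutamatergic synapses down.

    Pass ``glu_factor=1`` for the GABA-only arm or ``gaba_factor=1`` for the
    glutamate-only arm.
    """
    if gaba_factor <= 0 or glu_factor <= 0:
        raise ValueError("scale factors must be positive")
    cfg = _scale_sys(cfg, GABAERGIC_SYNAPSES, gaba_factor)
    return _scale_sys(cfg, GLUTAMATERGIC_SYNAPSES, glu_factor)


def preset_kcna1(cfg: SimulationConfig, dt_ii_factor: float = 0.5) -> SimulationConfig:
    """Lower the inhibitory-interneuron threshold (basket-cell hyperexcitability)."""
    if not (0.0 < dt_ii_factor <= 1.0):
        raise ValueError("dt_ii_factor must be in (0, 1]")
    if dt_ii_factor == 1.0:
        return cfg
    overrides = dict(cfg.dt_overrides)
    overrides["ii"] = cfg.effective_dt("ii") * dt_ii_factor
    return cfg.replace(dt_overrides=overrides)


def preset_cacna1a(cfg: SimulationConfig, variant: str) -> SimulationConfig:
    """Apply the tottering (mild) or rocker (severe) CaV2.1 mutation."""
    if variant not in CACNA1A_FACTORS:
        raise ValueError(
            f"unknown CACNA1A variant {variant!r}; expected one of "
            f"{sorted(CACNA1A_FACTORS)}"
        )
    return _scale_sys(cfg, CACNA1A_SYNAPSES, CACNA1A_FACTORS[variant])


def preset_dcn_bias(cfg: SimulationConfig, dt_dcn_delta: float) -> SimulationConfig:
    """Shift the DCN threshold: positive delta = tonic inhibition (lower DCN
    firing, gravity compensation); negative = disinhibition."""
    new_dt = cfg.effective_dt("dcn") + dt_dcn_delta
    if new_dt < 0:
        raise ValueError(f"resulting DT_dcn would be negative ({new_dt:.4g})")
    if dt_dcn_delta == 0.0:
        return cfg
    overrides = dict(cfg.dt_overrides)
    overrides["dcn"] = new_dt
    return cfg.replace(dt_overrides=overrides)
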