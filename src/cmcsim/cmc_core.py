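"""One-sample Boolean update of the cerebellar micro complex (CmC).

Each CmC contains a mossy-fibre and a climbing-fibre afferent, a granule
cell, a Golgi cell, an inhibitory interneuron, a Purkinje cell and a deep
cerebellar nucleus (DCN) neuron.  Every synapse contributes, when its
presynaptic neuron is active, a drive ``X * SyS`` with a fresh uniform draw
``X ~ U[0, 1)``; the postsynaptic neuron fires iff the signed sum of drives
exceeds its depolarisation threshold DT.  Updates run in a fixed order within
each sample (granule -> Golgi -> interneuron -> Purkinje -> DCN); the Golgi
cell inhibits the granule cell with one sample of delay, which is the only
state carried between samples.

All operations are vectorized across ``n`` parallel, non-communicating CmCs.
Reproducibility contract: draws are consumed in the fixed synapse order below
and only for array elements whose presynaptic neuron is active, so a run is
bit-for-bit determined by (seed, parameters, inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CIRCUIT_SYNAPSES",
    "CIRCUIT_NEURONS",
    "GABAERGIC_SYNAPSES",
    "GLUTAMATERGIC_SYNAPSES",
    "SynapticParams",
    "CmCState",
    "masked_drive",
    "step_granule",
    "step_golgi",
    "step_interneuron",
    "step_purkinje",
    "step_dcn",
    "step_cmc_population",
]

#: Canonical synapse names, in RNG consumption order within a sample.
CIRCUIT_SYNAPSES = (
    "mf_granule",
    "golgi_granule",
    "granule_golgi",
    "granule_ii",
    "granule_purkinje",
    "cf_purkinje",
    "ii_purkinje",
    "mf_dcn",
    "cf_dcn",
    "purkinje_dcn",
)

CIRCUIT_NEURONS = ("granule", "golgi", "ii", "purkinje", "dcn")

#: Inhibitory (GABAergic) synapses: Golgi, interneuron and Purkinje efferents.
GABAERGIC_SYNAPSES = ("golgi_granule", "ii_purkinje", "purkinje_dcn")
GLUTAMATERGIC_SYNAPSES = tuple(s for s in CIRCUIT_SYNAPSES if s not in GABAERGIC_SYNAPSES)


@dataclass
class SynapticParams:
    """Per-CmC synaptic strengths (SyS) and thresholds (DT).

    Values are stored as length-``n`` arrays even when homogeneous, because
    plasticity makes them diverge per circuit.  SyS >= 0; DT >= 0.
    """

    sys: dict[str, np.ndarray]
    dt: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name in CIRCUIT_SYNAPSES:
            if name not in self.sys:
                raise ValueError(f"missing SyS entry: {name}")
        for name in CIRCUIT_NEURONS:
            if name not in self.dt:
                raise ValueError(f"missing DT entry: {name}")
        self.sys = {k: np.asarray(v, dtype=float) for k, v in self.sys.items()}
        self.dt = {k: np.asarray(v, dtype=float) for k, v in self.dt.items()}
        for k, v in {**self.sys, **self.dt}.items():
            if np.any(v < 0):
                raise ValueError(f"{k}: SyS and DT must be >= 0")

    @property
    def n(self) -> int:
        return self.sys["mf_granule"].shape[0]

    @classmethod
    def homogeneous(
        cls,
        n: int,
        sys_default: float = 1.5,
        dt_default: float = 0.15,
        sys_overrides: dict[str, float] | None = None,
        dt_overrides: dict[str, float] | None = None,
    ) -> "SynapticParams":
        sys_overrides = sys_overrides or {}
        dt_overrides = dt_overrides or {}
        unknown = (set(sys_overrides) - set(CIRCUIT_SYNAPSES)) | (
            set(dt_overrides) - set(CIRCUIT_NEURONS)
        )
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        sys = {
            s: np.full(n, sys_overrides.get(s, sys_default), dtype=float)
            for s in CIRCUIT_SYNAPSES
        }
        dt = {
            m: np.full(n, dt_overrides.get(m, dt_default), dtype=float)
            for m in CIRCUIT_NEURONS
        }
        return cls(sys=sys, dt=dt)

    def copy(self) -> "SynapticParams":
        return SynapticParams(
            sys={k: v.copy() for k, v in self.sys.items()},
            dt={k: v.copy() for k, v in self.dt.items()},
        )


@dataclass
class CmCState:
    """Boolean firing state of every circuit neuron at one sample."""

    mossy_fibre: np.ndarray
    climbing_fibre: np.ndarray
    granule: np.ndarray
    golgi: np.ndarray
    inhibitory_interneuron: np.ndarray
    purkinje: np.ndarray
    dcn: np.ndarray
    golgi_prev: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def zeros(cls, n: int) -> "CmCState":
        z = lambda: np.zeros(n, dtype=np.uint8)  # noqa: E731
        return cls(z(), z(), z(), z(), z(), z(), z(), golgi_prev=z())


def masked_drive(
    active: np.ndarray, sys: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-CmC drive ``X * SyS`` where the presynaptic neuron is active, else 0.

    Draws are consumed only for active elements, keeping RNG use well-defined.
    ``sys`` may be a scalar or a length-n array.
    """
    active = np.asarray(active)
    out = np.zeros(active.shape[0], dtype=float)
    idx = np.flatnonzero(active)
    if idx.size:
        sys = np.asarray(sys, dtype=float)
        out[idx] = rng.random(idx.size) * (sys[idx] if sys.ndim else sys)
    return out


def _check_lengths(n: int, *vecs: np.ndarray) -> None:
    for v in vecs:
        if np.asarray(v).shape[0] != n:
            raise ValueError("input vectors must all have length n")


def step_granule(
    mossy: np.ndarray,
    golgi_prev: np.ndarray,
    params: SynapticParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Granule cell: mossy excitation minus delayed Golgi inhibition."""
    n = params.n
    _check_lengths(n, mossy, golgi_prev)
    drive = masked_drive(mossy, params.sys["mf_granule"], rng)
    drive -= masked_drive(golgi_prev, params.sys["golgi_granule"], rng)
    return (drive > params.dt["granule"]).astype(np.uint8)


def step_golgi(
    granule: np.ndarray, params: SynapticParams, rng: np.random.Generator
) -> np.ndarray:
    """Golgi cell: excited by the granule cell of the same sample."""
    n = params.n
    _check_lengths(n, granule)
    drive = masked_drive(granule, params.sys["granule_golgi"], rng)
    return (drive > params.dt["golgi"]).astype(np.uint8)


def step_interneuron(
    granule: np.ndarray, params: SynapticParams, rng: np.random.Generator
) -> np.ndarray:
    """Inhibitory interneuron: excited by the granule cell (parallel fibre)."""
    n = params.n
    _check_lengths(n, granule)
    drive = masked_drive(granule, params.sys["granule_ii"], rng)
    return (drive > params.dt["ii"]).astype(np.uint8)


def step_purkinje(
    granule: np.ndarray,
    climbing: np.ndarray,
    interneuron: np.ndarray,
    params: SynapticParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Purkinje cell: parallel-fibre + climbing-fibre excitation, interneuron inhibition."""
    n = params.n
    _check_lengths(n, granule, climbing, interneuron)
    drive = masked_drive(granule, params.sys["granule_purkinje"], rng)
    drive += masked_drive(climbing, params.sys["cf_purkinje"], rng)
    drive -= masked_drive(interneuron, params.sys["ii_purkinje"], rng)
    return (drive > params.dt["purkinje"]).astype(np.uint8)


def step_dcn(
    mossy: np.ndarray,
    climbing: np.ndarray,
    purkinje: np.ndarray,
    params: SynapticParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """DCN: direct afferent excitation minus Purkinje inhibition."""
    n = params.n
    _check_lengths(n, mossy, climbing, purkinje)
    drive = masked_drive(mossy, params.sys["mf_dcn"], rng)
    drive += masked_drive(climbing, params.sys["cf_dcn"], rng)
    drive -= masked_drive(purkinje, params.sys["purkinje_dcn"], rng)
    return (drive > params.dt["dcn"]).astype(np.uint8)


def step_cmc_population(
    mossy: np.ndarray,
    climbing: np.ndarray,
    state: CmCState,
    params: SynapticParams,
    rng: np.random.Generator,
) -> CmCState:
    """Advance the whole circuit by one sample.

    The neuron updates run in their fixed within-sample order; the returned
    state carries the new Golgi vector as ``golgi_prev`` for the next sample.
    """
    n = params.n
    _check_lengths(n, mossy, climbing, state.golgi_prev)
    granule = step_granule(mossy, state.golgi_prev, params, rng)
    golgi = step_golgi(granule, params, rng)
    interneuron = step_interneuron(granule, params, rng)
    purkinje = step_purkinje(granule, climbing, interneuron, params, rng)
    dcn = step_dcn(mossy, climbing, purkinje, params, rng)
    return CmCState(
        mossy_fibre=np.asarray(mossy, dtype=np.uint8),
        climbing_fibre=np.asarray(climbing, dtype=np.uint8),
        granule=granule,
        golgi=golgi,
        inhibitory_interneuron=interneuron,
        purkinje=purkinje,
        dcn=dcn,
        golgi_prev=golgi,
    )
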