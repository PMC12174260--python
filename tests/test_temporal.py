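"""Temporal-summation engine: decay, refractory lockout, memoryless limit."""

import numpy as np
import pytest

from cmcsim.cmc_core import CmCState, SynapticParams, step_cmc_population
from cmcsim.rate_coding import sample_afferent
from cmcsim.temporal import (
    MembraneState,
    TemporalConfig,
    decay_factor,
    run_temporal_cmc,
    step_temporal_neuron,
)


@pytest.mark.parametrize("refr,step,expected", [(3, 2, 1 / 3), (3, 3, 0.0), (4, 2, 0.5)])
def test_decay_factor(refr, step, expected):
    assert decay_factor(refr, step) == pytest.approx(expected)


def test_decay_factor_rejects_step_above_refractory():
    with pytest.raises(ValueError):
        decay_factor(3.0, 4.0)


def test_temporal_config_defaults():
    cfg = TemporalConfig()
    assert cfg.step_ms == pytest.approx(2.0)
    assert cfg.decay == pytest.approx(1 / 3)
    assert TemporalConfig(decay_override=2 / 3).decay == pytest.approx(2 / 3)


def test_neuron_idle_without_drive():
    fired, eff = step_temporal_neuron(np.zeros(3), np.zeros(3), 0.15, 1 / 3)
    assert fired.sum() == 0
    assert np.all(eff == 0.0)


def test_firing_imposes_negative_effect_and_lockout():
    drive = np.array([1.0])
    fired, eff = step_temporal_neuron(drive, np.zeros(1), 0.15, 1 / 3)
    assert fired[0] == 1
    assert eff[0] == pytest.approx(-1 / 3)
    # while the carried effect is negative the neuron cannot fire
    fired2, eff2 = step_temporal_neuron(np.array([5.0]), eff, 0.15, 1 / 3)
    assert fired2[0] == 0


def test_subthreshold_summation_hand_arithmetic():
    """Two successive 0.12 drives with decay 2/3 sum past DT=0.15; with
    decay 1/3 two 0.10 drives stay below it."""
    _, eff = step_temporal_neuron(np.array([0.12]), np.zeros(1), 0.15, 2 / 3)
    assert eff[0] == pytest.approx(0.08)
    fired, _ = step_temporal_neuron(np.array([0.12]), eff, 0.15, 2 / 3)
    assert fired[0] == 1  # 0.08 + 0.12 = 0.20 > 0.15

    _, eff = step_temporal_neuron(np.array([0.10]), np.zeros(1), 0.15, 1 / 3)
    fired, _ = step_temporal_neuron(np.array([0.10]), eff, 0.15, 1 / 3)
    assert fired[0] == 0  # 0.0333 + 0.10 < 0.15


def test_effect_stays_bounded(rng):
    params = SynapticParams.homogeneous(200)
    cfg = TemporalConfig()
    mem = MembraneState(200)
    assert mem.bounded()
    # heavy drive for many samples must keep |effect| <= 1 by construction
    carried = np.zeros(200)
    for _ in range(50):
        drive = rng.random(200) * 3.0 - 0.5
        _, carried = step_temporal_neuron(drive, carried, 0.15, 1 / 3)
        assert np.all(carried >= -1.0) and np.all(carried <= 1.0)


def test_silent_afferents_give_silent_raster(rng):
    params = SynapticParams.homogeneous(100)
    raster = run_temporal_cmc(np.zeros(30), np.zeros(30), params, TemporalConfig(), rng)
    for name in ("granule", "golgi", "ii", "purkinje", "dcn"):
        assert raster[name].sum() == 0


def test_no_refractory_violations(rng):
    """At 500 Hz with a 3 ms refractory period no neuron may fire on
    consecutive samples (2 ms apart)."""
    params = SynapticParams.homogeneous(300)
    probs = np.full(400, 0.4)
    raster = run_temporal_cmc(probs, probs, params, TemporalConfig(), rng)
    for name in ("granule", "golgi", "ii", "purkinje", "dcn"):
        consecutive = raster[name][1:] & raster[name][:-1]
        assert consecutive.sum() == 0


def test_decay_zero_limit_matches_non_temporal(rng):
    """With decay forced to 0 the temporal engine is memoryless and its
    per-sample statistics match the standard circuit."""
    n = 30_000
    params = SynapticParams.homogeneous(n)
    cfg = TemporalConfig(decay_override=0.0)
    probs = np.full(20, 0.5)
    raster = run_temporal_cmc(probs, probs, params, cfg, np.random.default_rng(11))

    state = CmCState.zeros(n)
    rng2 = np.random.default_rng(12)
    means = {k: [] for k in ("granule", "golgi", "ii", "purkinje", "dcn")}
    for t in range(20):
        mossy = sample_afferent(0.5, n, rng2)
        climbing = sample_afferent(0.5, n, rng2)
        state = step_cmc_population(mossy, climbing, state, params, rng2)
        means["granule"].append(state.granule.mean())
        means["golgi"].append(state.golgi.mean())
        means["ii"].append(state.inhibitory_interneuron.mean())
        means["purkinje"].append(state.purkinje.mean())
        means["dcn"].append(state.dcn.mean())
    for name in means:
        a = raster[name][5:].mean()
        b = np.mean(means[name][5:])
        se = np.sqrt(max(b * (1 - b), 1e-6) / (15 * n))
        assert abs(a - b) < 5 * se, name


def test_cross_model_rate_consistency():
    """Temporal (500 Hz) and non-temporal (250 Hz) engines at matched input
    rates produce similar output frequencies (within 20% relative).  At
    moderate afferent rates the refractory occupancy is small; at high rates
    the lockout systematically depresses the temporal engine further."""
    n = 20_000
    params = SynapticParams.homogeneous(n)
    freq = 30.0  # Hz afferent rate
    raster = run_temporal_cmc(
        np.full(60, freq / 500.0), np.full(60, freq / 500.0), params,
        TemporalConfig(), np.random.default_rng(21),
    )
    temporal_hz = raster["dcn"][10:].mean() * 500.0

    state = CmCState.zeros(n)
    rng = np.random.default_rng(22)
    vals = []
    for t in range(30):
        mossy = sample_afferent(freq / 250.0, n, rng)
        climbing = sample_afferent(freq / 250.0, n, rng)
        state = step_cmc_population(mossy, climbing, state, params, rng)
        if t >= 5:
            vals.append(state.dcn.mean())
    non_temporal_hz = np.mean(vals) * 250.0
    assert temporal_hz == pytest.approx(non_temporal_hz, rel=0.2)
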