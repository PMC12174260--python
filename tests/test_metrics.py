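"""Tremor metric, firing rates, spectrogram, SCFH sweep, circuit-count search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmcsim.cmc_core import SynapticParams
from cmcsim.config import SimulationConfig
from cmcsim.metrics import (
    TremorConfig,
    firing_rate_moving_average,
    intention_tremor,
    morse_spectrogram,
    moving_mean,
    polynomial_requirement_fit,
    required_cmc_search,
    scfh_sweep,
)


def _reference_tremor(x, half_window=2):
    """Independent brute-force evaluation of the moving mean / moving
    variance definitions, nested loops and all."""
    n = len(x)
    mm = []
    for t in range(n):
        lo, hi = max(0, t - half_window), min(n, t + half_window + 1)
        mm.append(sum(x[lo:hi]) / (hi - lo))
    out = []
    for t in range(n):
        lo, hi = max(0, t - half_window), min(n, t + half_window + 1)
        out.append(sum(abs(x[i] - mm[i]) ** 2 for i in range(lo, hi)) / (hi - lo))
    return np.array(out)


def test_moving_mean_examples():
    assert np.allclose(moving_mean(np.full(7, 0.3)), 0.3)
    assert moving_mean(np.array([0.0, 1, 0, 1, 0]))[2] == pytest.approx(0.4)
    assert moving_mean(np.array([0.7]))[0] == pytest.approx(0.7)


def test_tremor_zero_iff_locally_constant():
    assert np.all(intention_tremor(np.full(20, 0.5)) == 0.0)
    trem = intention_tremor(np.array([0.0, 1, 0, 1, 0]))
    assert np.all(trem > 0)


@pytest.mark.parametrize("series", [
    [0.0, 1, 0, 1, 0],
    [0.1, 0.5, 0.2, 0.9, 0.4, 0.4, 0.7],
    list(np.sin(np.linspace(0, 3, 17)) * 0.4 + 0.5),
])
def test_tremor_matches_brute_force_reference(series):
    np.testing.assert_allclose(
        intention_tremor(np.array(series)), _reference_tremor(series), atol=1e-12
    )


@given(scale=st.floats(0.1, 5.0))
@settings(max_examples=30, derandomize=True)
def test_tremor_quadratic_homogeneity(scale):
    x = np.array([0.1, 0.9, 0.3, 0.7, 0.2, 0.8, 0.5])
    np.testing.assert_allclose(
        intention_tremor(scale * x), scale**2 * intention_tremor(x), rtol=1e-9
    )


def test_firing_rate_moving_average(rng):
    assert np.allclose(firing_rate_moving_average(np.ones(100), 25, 250.0), 250.0)
    assert np.allclose(firing_rate_moving_average(np.zeros(100), 25, 250.0), 0.0)
    raster = (rng.random(20_000) < 0.4).astype(float)
    rates = firing_rate_moving_average(raster, 2001, 250.0)
    assert rates[10_000] == pytest.approx(100.0, abs=5.0)


def test_spectrogram_tone_ridge():
    fs = 250.0
    t = np.arange(1500) / fs
    tone = np.sin(2 * np.pi * 40.0 * t)
    freqs, times, mag = morse_spectrogram(tone, fs)
    ridge_freqs = freqs[np.argmax(mag[:, 300:1200], axis=0)]
    # energy concentrates at the tone frequency away from the edges
    assert np.median(ridge_freqs) == pytest.approx(40.0, rel=0.08)


def test_spectrogram_zero_series_and_short_series():
    freqs, times, mag = morse_spectrogram(np.zeros(1000), 250.0)
    assert np.allclose(mag, 0.0)
    with pytest.raises(ValueError):
        morse_spectrogram(np.zeros(100), 250.0)  # under one cycle of 0.5 Hz


def test_spectrogram_noise_has_no_stable_ridge(rng):
    fs = 250.0
    t = np.arange(1500) / fs
    tone = np.sin(2 * np.pi * 40.0 * t)
    noise = (rng.random(1500) < 0.3).astype(float)
    stab = []
    for x in (tone, noise):
        _, _, mag = morse_spectrogram(x, fs)
        ridge = np.argmax(mag[:, 300:1200], axis=0)
        stab.append(np.std(ridge))
    assert stab[0] < stab[1]  # the tone ridge is steadier than the noise ridge


# --------------------------------------------------------------------------
# SCFH sweep


@pytest.fixture(scope="module")
def analytic_grid():
    return scfh_sweep(SynapticParams.homogeneous(1))


def test_scfh_monotone_in_both_afferents(analytic_grid):
    dcn = analytic_grid.dcn_prob
    assert np.all(np.diff(dcn, axis=1) >= -1e-12)
    assert np.all(np.diff(dcn, axis=0) >= -1e-12)


def test_scfh_origin_cell_is_quiet(analytic_grid):
    assert analytic_grid.dcn_prob[0, 0] == pytest.approx(0.0)
    assert analytic_grid.abs_diff[0, 0] == pytest.approx(0.0)


def test_scfh_symmetry_about_central_curve(analytic_grid):
    """|DCN - CF| is approximately symmetric about the central-frequency
    curve (bound frozen from reference runs of the analytic path)."""
    g = analytic_grid
    stats = []
    for i in range(g.cf_probs.size):
        j = int(np.argmin(g.abs_diff[i]))
        for k in range(1, min(j, g.mf_probs.size - 1 - j) + 1):
            hi, lo = g.abs_diff[i, j + k], g.abs_diff[i, j - k]
            if hi + lo > 1e-6:
                stats.append(abs(hi - lo) / (hi + lo))
    assert np.mean(stats) < 0.2


def test_scfh_central_curve_shifts_with_synaptic_weights(analytic_grid):
    stronger = scfh_sweep(
        SynapticParams.homogeneous(1, sys_overrides={"purkinje_dcn": 3.0})
    )
    base_curve = analytic_grid.central_curve
    up_curve = stronger.central_curve
    assert np.any(up_curve != base_curve)
    # stronger Purkinje inhibition needs more mossy drive to match CF
    assert up_curve.sum() > base_curve.sum()


def test_scfh_simulation_path_agrees_with_analytic(rng):
    mf = cf = np.array([0.2, 0.5, 0.8])
    n = 30_000
    sim = scfh_sweep(
        SynapticParams.homogeneous(n), mf, cf,
        method="simulation", samples_per_cell=50, rng=rng,
    )
    exact = scfh_sweep(SynapticParams.homogeneous(1), mf, cf)
    se = np.sqrt(np.maximum(exact.dcn_prob * (1 - exact.dcn_prob), 1e-6) / (40 * n))
    assert np.all(np.abs(sim.dcn_prob - exact.dcn_prob) < 5 * se)


def test_scfh_long_format_frame(analytic_grid):
    df = analytic_grid.to_frame()
    assert list(df.columns) == ["mf_prob", "cf_prob", "dcn_prob", "abs_diff"]
    assert len(df) == analytic_grid.dcn_prob.size


# --------------------------------------------------------------------------
# minimum circuit count


def test_required_cmc_monotone_in_muscle_strength():
    """Stronger muscles need more parallel circuits for smooth movement."""
    cfg = SimulationConfig(n_cmc=100, n_samples=300)
    table = required_cmc_search(
        [2.0, 8.0], cfg, reference_n=4000, k=2, n_start=50, n_cap=16_000, seed=3
    )
    assert not table["censored"].any()
    req = table.set_index("muscle_strength")["required_n"]
    assert req[8.0] >= req[2.0]


def test_polynomial_requirement_fit():
    import pandas as pd

    table = pd.DataFrame(
        {"muscle_strength": [1, 2, 3, 4], "required_n": [10, 40, 90, 160],
         "censored": [False] * 4}
    )
    coeffs = polynomial_requirement_fit(table, degree=2)
    fitted = np.polyval(coeffs, table["muscle_strength"])
    np.testing.assert_allclose(fitted, table["required_n"], atol=1e-6)
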