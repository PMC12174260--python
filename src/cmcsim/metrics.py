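"""Analysis metrics: intention tremor, firing rates, spectrograms and sweeps.

Intention tremor is the centred moving variance of the joint position: the
windowed mean of squared deviations of each sample from its own centred
moving mean (default window 5 samples, half-window 2).  Window edges are
truncated to the available samples with the divisor equal to the count
actually summed.

The spectrogram uses generalized Morse wavelets (gamma = 3, time-bandwidth
P^2 = 120) evaluated in the frequency domain over 0.5-100 Hz, the standard
choice for spike-train time-frequency maps at these sampling rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cmc_core import CmCState, SynapticParams, step_cmc_population
from .config import SimulationConfig
from .motor_plant import run_closed_loop
from .oracle import dcn_marginal
from .rate_coding import prob_to_freq, sample_afferent

__all__ = [
    "TremorConfig",
    "moving_mean",
    "intention_tremor",
    "firing_rate_moving_average",
    "morse_spectrogram",
    "ScfhGrid",
    "scfh_sweep",
    "required_cmc_search",
]


@dataclass(frozen=True)
class TremorConfig:
    """Moving-variance window for the intention-tremor metric."""

    half_window: int = 2

    @property
    def window(self) -> int:
        return 2 * self.half_window + 1


def moving_mean(series: np.ndarray, cfg: TremorConfig = TremorConfig()) -> np.ndarray:
    """Centred moving mean with truncated edges (adaptive divisor)."""
    s = pd.Series(np.asarray(series, dtype=float))
    if s.empty:
        raise ValueError("series must be non-empty")
    return s.rolling(cfg.window, center=True, min_periods=1).mean().to_numpy()


def intention_tremor(
    series: np.ndarray, cfg: TremorConfig = TremorConfig()
) -> np.ndarray:
    """Windowed variance of the series around its own moving mean.

    Zero everywhere iff the series is constant within every window.
    """
    x = np.asarray(series, dtype=float)
    dev2 = (x - moving_mean(x, cfg)) ** 2
    return (
        pd.Series(dev2).rolling(cfg.window, center=True, min_periods=1).mean().to_numpy()
    )


def firing_rate_moving_average(
    raster: np.ndarray, window: int, sampling: float
) -> np.ndarray:
    """Boxcar-smoothed firing rate of a Boolean spike series, in Hz."""
    probs = (
        pd.Series(np.asarray(raster, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return prob_to_freq(probs, sampling)


# --------------------------------------------------------------------------
# generalized Morse wavelet spectrogram


def morse_spectrogram(
    series: np.ndarray,
    sampling: float,
    freq_range: tuple[float, float] = (0.5, 100.0),
    gamma: float = 3.0,
    time_bandwidth: float = 120.0,
    voices_per_octave: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous wavelet transform magnitude with generalized Morse wavelets.

    Returns ``(freqs_hz, times_s, magnitude)`` with ``magnitude`` of shape
    (n_freqs, n_samples).  The wavelet is evaluated analytically in the
    frequency domain: ``psi(w) ~ w^beta exp(-w^gamma)`` with
    ``beta = time_bandwidth / gamma``, peak-normalised.
    """
    x = np.asarray(series, dtype=float)
    f_lo, f_hi = freq_range
    if not (0 < f_lo < f_hi <= sampling / 2):
        raise ValueError("need 0 < f_lo < f_hi <= Nyquist")
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size * (1.0 / sampling) < 1.0 / f_lo:
        raise ValueError(
            "series too short: must span at least one cycle of the lowest "
            f"analysis frequency ({f_lo} Hz)"
        )
    n = x.size
    beta = time_bandwidth / gamma
    w_peak = (beta / gamma) ** (1.0 / gamma)

    n_octaves = np.log2(f_hi / f_lo)
    n_freqs = max(int(np.ceil(n_octaves * voices_per_octave)) + 1, 2)
    freqs = f_lo * 2.0 ** (np.linspace(0.0, n_octaves, n_freqs))

    xf = np.fft.fft(x)
    w = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0)  # digital angular frequency
    coef = np.empty((n_freqs, n), dtype=complex)
    pos = w > 0
    for i, f in enumerate(freqs):
        scale = w_peak / (2.0 * np.pi * f / sampling)
        arg = scale * w[pos]
        with np.errstate(divide="ignore"):
            log_psi = (
                beta * (np.log(arg) - np.log(w_peak)) - (arg**gamma - w_peak**gamma)
            )
        psi = np.zeros(n)
        psi[pos] = 2.0 * np.exp(log_psi)
        coef[i] = np.fft.ifft(xf * psi)
    times = np.arange(n) / sampling
    return freqs, times, np.abs(coef)


# --------------------------------------------------------------------------
# SCFH input-grid sweep


@dataclass
class ScfhGrid:
    """Mean DCN output over a grid of afferent firing probabilities.

    ``dcn_prob[i, j]`` is the DCN firing probability at climbing-fibre
    probability ``cf_probs[i]`` and mossy-fibre probability ``mf_probs[j]``;
    ``abs_diff`` is ``|DCN - CF|`` in the same probability units and
    ``central_curve[i]`` the mossy probability minimising it for each CF row.
    """

    mf_probs: np.ndarray
    cf_probs: np.ndarray
    dcn_prob: np.ndarray
    abs_diff: np.ndarray
    central_curve: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: mf_prob, cf_prob, dcn_prob, abs_diff."""
        mf, cf = np.meshgrid(self.mf_probs, self.cf_probs)
        return pd.DataFrame(
            {
                "mf_prob": mf.ravel(),
                "cf_prob": cf.ravel(),
                "dcn_prob": self.dcn_prob.ravel(),
                "abs_diff": self.abs_diff.ravel(),
            }
        )


def _simulated_dcn_prob(
    mf: float,
    cf: float,
    params: SynapticParams,
    samples: int,
    rng: np.random.Generator,
    burn_in: int = 10,
) -> float:
    state = CmCState.zeros(params.n)
    means = []
    for t in range(samples):
        mossy = sample_afferent(mf, params.n, rng)
        climbing = sample_afferent(cf, params.n, rng)
        state = step_cmc_population(mossy, climbing, state, params, rng)
        if t >= burn_in:
            means.append(float(state.dcn.mean()))
    if not means:
        raise ValueError("samples must exceed the burn-in")
    return float(np.mean(means))


def scfh_sweep(
    params: SynapticParams | None = None,
    mf_probs: np.ndarray | None = None,
    cf_probs: np.ndarray | None = None,
    *,
    method: str = "analytic",
    n_cmc: int = 100_000,
    samples_per_cell: int = 60,
    rng: np.random.Generator | None = None,
) -> ScfhGrid:
    """Sweep the (mossy, climbing) probability grid and extract the central curve.

    ``method='analytic'`` uses the stationary marginal (requires homogeneous
    ``params``); ``method='simulation'`` runs the circuit for
    ``samples_per_cell`` samples per cell on ``n_cmc`` parallel CmCs,
    discarding a 10-sample burn-in.
    """
    mf_probs = np.linspace(0, 1, 21) if mf_probs is None else np.asarray(mf_probs)
    cf_probs = np.linspace(0, 1, 21) if cf_probs is None else np.asarray(cf_probs)
    dcn = np.empty((cf_probs.size, mf_probs.size))
    if method == "analytic":
        for i, cf in enumerate(cf_probs):
            for j, mf in enumerate(mf_probs):
                dcn[i, j] = dcn_marginal(float(mf), float(cf), params)
    elif method == "simulation":
        if params is None:
            params = SynapticParams.homogeneous(n_cmc)
        if rng is None:
            rng = np.random.default_rng(0)
        for i, cf in enumerate(cf_probs):
            for j, mf in enumerate(mf_probs):
                dcn[i, j] = _simulated_dcn_prob(
                    float(mf), float(cf), params, samples_per_cell, rng
                )
    else:
        raise ValueError(f"unknown method {method!r}")
    abs_diff = np.abs(dcn - cf_probs[:, None])
    central = mf_probs[np.argmin(abs_diff, axis=1)]
    return ScfhGrid(mf_probs, cf_probs, dcn, abs_diff, central)


# --------------------------------------------------------------------------
# minimum circuit count for smooth movement


def run_tremor_trial(
    cfg: SimulationConfig,
    n_cmc: int,
    muscle_strength: float,
    seed: int,
    tremor_cfg: TremorConfig = TremorConfig(),
) -> float:
    """One closed-loop run; returns the time-mean intention tremor."""
    motor = cfg.motor.copy()
    motor.muscle_strength = muscle_strength
    params = cfg.build_params(n_cmc)
    rec = run_closed_loop(
        cfg.build_trajectory(),
        params,
        motor,
        cfg.rate_config(),
        np.random.default_rng(seed),
    )
    return float(np.mean(intention_tremor(rec["actual"].to_numpy(), tremor_cfg)))


def required_cmc_search(
    strengths,
    cfg: SimulationConfig,
    *,
    threshold: float | None = None,
    reference_n: int | None = None,
    k: int = 3,
    n_start: int = 50,
    n_cap: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Minimal circuit count reaching a low-tremor threshold per muscle strength.

    The threshold defaults to the mean tremor of a reference run at
    ``reference_n`` circuits with the config's own muscle strength (the
    smooth-movement regime).  "Consistently reached" means all ``k`` seeded
    replicates meet it.  Doubling locates a bracket, bisection refines it;
    strengths that fail at ``n_cap`` are reported as censored.
    """
    if threshold is None:
        if reference_n is None:
            raise ValueError("give either threshold or reference_n")
        threshold = run_tremor_trial(
            cfg, reference_n, cfg.motor.muscle_strength, seed=seed
        )

    def consistent(n: int, strength: float) -> bool:
        return all(
            run_tremor_trial(cfg, n, strength, seed=seed + 1000 * r + n)
            <= threshold
            for r in range(k)
        )

    rows = []
    for strength in strengths:
        strength = float(strength)
        n = n_start
        if consistent(n, strength):
            rows.append({"muscle_strength": strength, "required_n": n, "censored": False})
            continue
        lo = n
        while True:
            n *= 2
            if n >= n_cap:
                if consistent(n_cap, strength):
                    lo, n = lo, n_cap
                    break
                rows.append(
                    {"muscle_strength": strength, "required_n": n_cap, "censored": True}
                )
                n = None
                break
            if consistent(n, strength):
                break
            lo = n
        if n is None:
            continue
        hi = n
        while hi - lo > max(1, lo // 8):  # ~12% resolution
            mid = (lo + hi) // 2
            if consistent(mid, strength):
                hi = mid
            else:
                lo = mid
        rows.append({"muscle_strength": strength, "required_n": hi, "censored": False})
    return pd.DataFrame(rows)


def polynomial_requirement_fit(table: pd.DataFrame, degree: int = 6) -> np.ndarray:
    """Polynomial fit of required circuit count against muscle strength."""
    t = table[~table["censored"]]
    deg = min(degree, max(len(t) - 1, 1))
    return np.polyfit(t["muscle_strength"], t["required_n"], deg)
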