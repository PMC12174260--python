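"""Seeded experiment runners for the standard study pipelines.

Each runner builds its configuration from the model defaults plus caller
overrides, executes the corresponding simulation at a configurable scale and
writes columnar CSV outputs plus a JSON run manifest (effective config, seed,
library versions, wall time).  Runners default to a reduced scale (10^4
parallel circuits, <= 2500 samples) so the whole set completes in minutes on
one CPU; ``paper_scale=True`` restores the printed circuit counts.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cmc_core import CmCState, step_cmc_population
from .config import SimulationConfig
from .metrics import (
    firing_rate_moving_average,
    intention_tremor,
    morse_spectrogram,
    required_cmc_search,
    scfh_sweep,
)
from .motor_plant import run_closed_loop, sinusoid_trajectory
from .perturbations import (
    preset_cacna1a,
    preset_dcn_bias,
    preset_ethanol,
    preset_kcna1,
    preset_neocerebellar,
)
from .plasticity import PlasticityState
from .rate_coding import encode_position, sample_afferent
from .temporal import TemporalConfig, run_temporal_cmc

__all__ = ["EXPERIMENTS", "run_experiment"]

#: Default external-force magnitude (position-units per sample) for the
#: compensation / adaptation experiments; negative = towards extension.
DEFAULT_FORCE = 0.002

#: Default DCN threshold shift used by the force-compensation preset.
DEFAULT_DCN_DELTA = 0.05


def _manifest(outdir: Path, name: str, cfg: SimulationConfig, seed: int, t0: float,
              extra: dict | None = None) -> Path:
    payload = {
        "experiment": name,
        "seed": seed,
        "config": cfg.to_dict(),
        "versions": {
            "cmcsim": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "wall_time_s": round(time.time() - t0, 3),
    }
    if extra:
        payload.update(extra)
    path = outdir / f"{name}_manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=float))
    return path


def _single_cmc_rasters(
    cfg: SimulationConfig, seed: int, temporal: bool = False
) -> pd.DataFrame:
    """Open-loop single-circuit rasters over one flexion/extension cycle."""
    rate_cfg = cfg.rate_config()
    sampling = 500.0 if temporal else cfg.sampling_frequency_hz
    n_samples = cfg.n_samples
    position = sinusoid_trajectory(
        n_samples, sampling_hz=sampling, **{
            k: v for k, v in cfg.trajectory.items() if k != "kind"
        },
    )
    probs = np.array([encode_position(p, rate_cfg) for p in position])
    rng = np.random.default_rng(seed)
    params = cfg.build_params(1)
    out = {"t": np.arange(n_samples), "position": position}
    if temporal:
        raster = run_temporal_cmc(probs, probs, params, TemporalConfig(), rng)
        for key in ("mossy_fibre", "climbing_fibre", "granule", "golgi", "ii",
                    "purkinje", "dcn"):
            out[key] = raster[key][:, 0]
    else:
        state = CmCState.zeros(1)
        keys = ("mossy_fibre", "climbing_fibre", "granule", "golgi", "ii",
                "purkinje", "dcn")
        cols = {k: np.zeros(n_samples, dtype=np.uint8) for k in keys}
        for t in range(n_samples):
            mossy = sample_afferent(float(probs[t]), 1, rng)
            climbing = sample_afferent(float(probs[t]), 1, rng)
            state = step_cmc_population(mossy, climbing, state, params, rng)
            cols["mossy_fibre"][t] = state.mossy_fibre[0]
            cols["climbing_fibre"][t] = state.climbing_fibre[0]
            cols["granule"][t] = state.granule[0]
            cols["golgi"][t] = state.golgi[0]
            cols["ii"][t] = state.inhibitory_interneuron[0]
            cols["purkinje"][t] = state.purkinje[0]
            cols["dcn"][t] = state.dcn[0]
        out.update(cols)
    df = pd.DataFrame(out)
    window = max(int(sampling // 10), 5)
    for key in ("granule", "golgi", "ii", "purkinje", "dcn"):
        df[f"rate_{key}_hz"] = firing_rate_moving_average(
            df[key].to_numpy(), window, sampling
        )
    return df


def _write_spectrogram(path: Path, freqs, times, mag) -> None:
    """Dense CSV: first row times (s), first column frequencies (Hz)."""
    header = ",".join(["freq_hz\\time_s"] + [f"{t:.6g}" for t in times])
    rows = [header]
    for f, row in zip(freqs, mag):
        rows.append(",".join([f"{f:.6g}"] + [f"{v:.6g}" for v in row]))
    path.write_text("\n".join(rows) + "\n")


# --------------------------------------------------------------------------
# runners


def _run_single_circuit(cfg, seed, outdir, paper_scale):
    df = _single_cmc_rasters(cfg, seed)
    path = outdir / "single_circuit_rasters.csv"
    df.to_csv(path, index=False)
    return {"rasters": path}


def _run_spectrograms(cfg, seed, outdir, paper_scale):
    conditions = {
        "temporal": (cfg, True),
        "non_temporal": (cfg, False),
        "kcna1": (preset_kcna1(cfg), False),
        "tottering": (preset_cacna1a(cfg, "tottering"), False),
        "rocker": (preset_cacna1a(cfg, "rocker"), False),
    }
    paths = {}
    for label, (ccfg, temporal) in conditions.items():
        df = _single_cmc_rasters(ccfg, seed, temporal=temporal)
        p = outdir / f"spectrogram_{label}_raster.csv"
        df.to_csv(p, index=False)
        sampling = 500.0 if temporal else ccfg.sampling_frequency_hz
        # short runs cannot resolve down to 0.5 Hz; raise the floor as needed
        f_lo = max(0.5, sampling / len(df))
        freqs, times, mag = morse_spectrogram(
            df["dcn"].to_numpy().astype(float), sampling, freq_range=(f_lo, 100.0)
        )
        sp = outdir / f"spectrogram_{label}_dcn.csv"
        _write_spectrogram(sp, freqs, times, mag)
        paths[label] = p
        paths[f"{label}_spectrogram"] = sp
    return paths


def _run_scfh_map(cfg, seed, outdir, paper_scale):
    settings = {
        "baseline": {},
        "purkinje_dcn_up": {"purkinje_dcn": cfg.sys_default * 2.0},
        "purkinje_dcn_down": {"purkinje_dcn": cfg.sys_default * 0.5},
    }
    paths = {}
    for label, overrides in settings.items():
        ccfg = cfg.replace(sys_overrides={**cfg.sys_overrides, **overrides})
        grid = scfh_sweep(ccfg.build_params(1))
        p = outdir / f"scfh_{label}.csv"
        grid.to_frame().to_csv(p, index=False)
        cp = outdir / f"scfh_central_curve_{label}.csv"
        pd.DataFrame(
            {"cf_prob": grid.cf_probs, "central_mf_prob": grid.central_curve}
        ).to_csv(cp, index=False)
        paths[label] = p
        paths[f"{label}_central"] = cp
    return paths


def _run_circuit_loss(cfg, seed, outdir, paper_scale):
    ladder = (100_000, 10_000, 1_000) if paper_scale else (10_000, 1_000, 100)
    paths = {}
    summaries = []
    desired = cfg.build_trajectory()
    for n in ladder:
        ccfg = preset_neocerebellar(cfg, n)
        rec = run_closed_loop(
            desired,
            ccfg.build_params(),
            ccfg.motor,
            ccfg.rate_config(),
            np.random.default_rng(seed),
        )
        rec["tremor"] = intention_tremor(rec["actual"].to_numpy())
        p = outdir / f"circuit_loss_run_n{n}.csv"
        rec.to_csv(p, index=False)
        paths[f"n{n}"] = p
        summaries.append(
            {
                "n_cmc": n,
                "median_tremor": float(np.median(rec["tremor"])),
                "mean_error": float(rec["error"].mean()),
            }
        )
    table = required_cmc_search(
        [2.0, 5.0, 10.0],
        cfg.replace(n_samples=min(cfg.n_samples, 500)),
        reference_n=ladder[0] // 2,
        k=2,
        n_cap=ladder[0],
        seed=seed,
    )
    tp = outdir / "circuit_loss_required_cmc.csv"
    table.to_csv(tp, index=False)
    sp = outdir / "circuit_loss_summary.csv"
    pd.DataFrame(summaries).to_csv(sp, index=False)
    paths["required_cmc"] = tp
    paths["summary"] = sp
    return paths


def _run_ethanol(cfg, seed, outdir, paper_scale):
    arms = {
        "baseline": cfg,
        "gaba_up": preset_ethanol(cfg, gaba_factor=1.5, glu_factor=1.0),
        "glu_down": preset_ethanol(cfg, gaba_factor=1.0, glu_factor=0.8),
        "combined": preset_ethanol(cfg, gaba_factor=1.5, glu_factor=0.8),
    }
    desired = cfg.build_trajectory()
    paths = {}
    rows = []
    for label, acfg in arms.items():
        rec = run_closed_loop(
            desired,
            acfg.build_params(),
            acfg.motor,
            acfg.rate_config(),
            np.random.default_rng(seed),
        )
        rec["tremor"] = intention_tremor(rec["actual"].to_numpy())
        p = outdir / f"ethanol_{label}.csv"
        rec.to_csv(p, index=False)
        paths[label] = p
        rows.append(
            {
                "arm": label,
                "median_tremor": float(np.median(rec["tremor"])),
                "mean_error": float(rec["error"].mean()),
            }
        )
    sp = outdir / "ethanol_summary.csv"
    pd.DataFrame(rows).to_csv(sp, index=False)
    paths["summary"] = sp
    return paths


def _run_force_compensation(cfg, seed, outdir, paper_scale):
    conditions = {
        "baseline": (cfg, 0.0),
        "gravity": (cfg, -DEFAULT_FORCE),
        "gravity_compensated": (preset_dcn_bias(cfg, +DEFAULT_DCN_DELTA), -DEFAULT_FORCE),
        "antigravity": (cfg, +DEFAULT_FORCE),
        "antigravity_compensated": (
            preset_dcn_bias(cfg, -DEFAULT_DCN_DELTA),
            +DEFAULT_FORCE,
        ),
    }
    desired = cfg.build_trajectory()
    paths = {}
    rows = []
    for label, (ccfg, force) in conditions.items():
        motor = ccfg.motor.copy()
        motor.force_on_joint = force
        rec = run_closed_loop(
            desired,
            ccfg.build_params(),
            motor,
            ccfg.rate_config(),
            np.random.default_rng(seed),
        )
        p = outdir / f"force_compensation_{label}.csv"
        rec.to_csv(p, index=False)
        paths[label] = p
        rows.append(
            {
                "condition": label,
                "mean_error": float(rec["error"].mean()),
                "mean_dcn": float(rec["mean_dcn"].mean()),
            }
        )
    sp = outdir / "force_compensation_summary.csv"
    pd.DataFrame(rows).to_csv(sp, index=False)
    paths["summary"] = sp
    return paths


def _run_adaptive(cfg, seed, outdir, paper_scale):
    # settle (plasticity reaches steady state), gravity step, release
    n_samples = max(cfg.n_samples, 3500)
    seg = n_samples // 7
    force = np.zeros(n_samples)
    force[3 * seg : 5 * seg] = -DEFAULT_FORCE  # gravitational phase
    desired = np.full(n_samples, 0.3)  # near-extension operating point
    params = cfg.build_params()
    plast = PlasticityState(params, cfg.plasticity)
    rec = run_closed_loop(
        desired,
        params,
        cfg.motor,
        cfg.rate_config(),
        np.random.default_rng(seed),
        plasticity=plast,
        force_schedule=force,
    )
    rec["force"] = force
    for name, value in plast.mean_sys(params).items():
        rec.attrs[name] = value
    p = outdir / "adaptive_run.csv"
    rec.to_csv(p, index=False)
    sp = outdir / "adaptive_final_sys.csv"
    pd.DataFrame([plast.mean_sys(params)]).to_csv(sp, index=False)
    return {"run": p, "final_sys": sp}


EXPERIMENTS = {
    "single-circuit": _run_single_circuit,
    "spectrograms": _run_spectrograms,
    "scfh-map": _run_scfh_map,
    "circuit-loss": _run_circuit_loss,
    "ethanol": _run_ethanol,
    "force-compensation": _run_force_compensation,
    "adaptive": _run_adaptive,
}


def run_experiment(
    name: str,
    overrides: dict | None = None,
    seed: int = 0,
    outdir: str | Path = "runs",
    paper_scale: bool = False,
) -> dict[str, Path]:
    """Execute one named pipeline and write its CSV outputs + manifest."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = SimulationConfig(
        n_cmc=100_000 if paper_scale else 10_000,
        n_samples=2500,
        seed=seed,
    )
    if overrides:
        base = SimulationConfig.from_dict({**base.to_dict(), **overrides})
    paths = EXPERIMENTS[name](base, seed, outdir, paper_scale)
    paths["manifest"] = _manifest(outdir, name, base, seed, t0)
    return paths
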