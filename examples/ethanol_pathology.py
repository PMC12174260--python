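"""Acute alcohol intoxication: GABA facilitation and glutamate inhibition.

Four arms — baseline, GABAergic synapses scaled up 1.5x, glutamatergic
synapses scaled down 0.8x, and both combined — each track the same
sinusoid; the script prints the mean movement error per arm.
"""

import numpy as np

from cmcsim import SimulationConfig, intention_tremor, preset_ethanol, run_closed_loop

base = SimulationConfig(n_cmc=10_000, n_samples=2500)  # one full cycle
arms = {
    "baseline": base,
    "GABA up (1.5x)": preset_ethanol(base, gaba_factor=1.5, glu_factor=1.0),
    "glutamate down (0.8x)": preset_ethanol(base, gaba_factor=1.0, glu_factor=0.8),
    "combined": preset_ethanol(base, gaba_factor=1.5, glu_factor=0.8),
}
desired = base.build_trajectory()
print(f"{'arm':<24}{'mean error':>12}{'median tremor':>16}")
for name, cfg in arms.items():
    rec = run_closed_loop(
        desired, cfg.build_params(), cfg.motor, cfg.rate_config(),
        np.random.default_rng(3),
    )
    trem = np.median(intention_tremor(rec["actual"].to_numpy()))
    print(f"{name:<24}{rec['error'].mean():>12.4f}{trem:>16.2e}")
print()
print("Shifting the GABA/glutamate balance displaces the DCN operating point")
print("away from the climbing-fibre-set centre, so every intoxicated arm")
print("tracks with a larger systematic error than baseline (dysmetria).")
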