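"""The temporal-summation engine: carried drive, decay and refractoriness.

At 500 Hz sampling each neuron carries its subthreshold drive to the next
2 ms sample, scaled by the linear decay factor (refractory - step)/refractory
= 1/3, and is locked out for one sample after firing (4 ms between spikes,
beyond the 3 ms absolute refractory period).
"""

import numpy as np

from cmcsim import SynapticParams, TemporalConfig, decay_factor, run_temporal_cmc

cfg = TemporalConfig()
print(f"sampling step {cfg.step_ms:.0f} ms, refractory {cfg.refractory_ms:.0f} ms, "
      f"decay factor {decay_factor(cfg.refractory_ms, cfg.step_ms):.3f}")

params = SynapticParams.homogeneous(2_000)
probs = np.full(500, 0.4)  # 200 Hz afferents
raster = run_temporal_cmc(probs, probs, params, cfg, np.random.default_rng(5))

print(f"{'neuron':<10}{'rate Hz':>9}{'refractory violations':>24}")
for name in ("granule", "golgi", "ii", "purkinje", "dcn"):
    rate = raster[name].mean() * cfg.sampling_frequency
    violations = int((raster[name][1:] & raster[name][:-1]).sum())
    print(f"{name:<10}{rate:>9.1f}{violations:>24}")
print()
print("No neuron ever fires on consecutive samples: the -1 membrane reset")
print("enforces the absolute refractory period while subthreshold drive")
print("still sums across samples.")
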