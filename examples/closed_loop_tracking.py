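"""Closed-loop position following and the tremor / circuit-count relationship.

The joint follows a slow sinusoid while the pooled output of n parallel
micro complexes drives the flexor/extensor balance.  Fewer circuits mean a
noisier population vote and visibly larger intention tremor.
"""

import numpy as np

from cmcsim import (
    MotorConfig,
    RateCodingConfig,
    SynapticParams,
    intention_tremor,
    run_closed_loop,
    sinusoid_trajectory,
)

desired = sinusoid_trajectory(1500)
for n_cmc in (100, 1_000, 10_000):
    rec = run_closed_loop(
        desired,
        SynapticParams.homogeneous(n_cmc),
        MotorConfig(),
        RateCodingConfig(),
        np.random.default_rng(7),
    )
    tremor = intention_tremor(rec["actual"].to_numpy())
    print(
        f"n_cmc={n_cmc:>6}: mean |error| {rec['error'].mean():.4f}   "
        f"median tremor {np.median(tremor):.2e}"
    )
print()
print("Each tenfold loss of circuits raises the windowed tremor by roughly")
print("an order of magnitude — the population vote no longer averages out")
print("the stochastic synapses, as in neocerebellar syndrome.")
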