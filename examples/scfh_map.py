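"""Shifting central frequency: DCN output over the afferent input grid.

The analytic stationary marginal maps mean DCN firing probability over all
(mossy, climbing) input combinations.  The climbing fibre sets a central
output level; the mossy-minus-climbing difference shifts the DCN output
symmetrically around it, and changing the Purkinje->DCN weight moves the
central curve — the proposed locus of motor learning.
"""

import numpy as np

from cmcsim import SynapticParams, scfh_sweep

grid = scfh_sweep(SynapticParams.homogeneous(1))
print("DCN firing probability (rows: climbing fibre, cols: mossy fibre):")
idx = range(0, 21, 5)
header = "cf\\mf " + " ".join(f"{grid.mf_probs[j]:>6.2f}" for j in idx)
print(header)
for i in idx:
    row = " ".join(f"{grid.dcn_prob[i, j]:>6.3f}" for j in idx)
    print(f"{grid.cf_probs[i]:>5.2f} {row}")

print("\ncentral curve (mossy probability where DCN output matches CF):")
print(np.round(grid.central_curve[::5], 2))

shifted = scfh_sweep(SynapticParams.homogeneous(1, sys_overrides={"purkinje_dcn": 3.0}))
print("same curve with doubled Purkinje->DCN inhibition:")
print(np.round(shifted.central_curve[::5], 2))
print()
print("Output rises with both afferents; stronger Purkinje inhibition needs")
print("more mossy drive to reach the same centre — the curve shifts right.")
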