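"""Fourier shell correlation between two synthetic half-maps.

Renders the same toy transporter twice with independent 10% noise (the
half-map construction used for resolution estimation) and reports the
resolution at the FSC = 0.143 criterion.
"""

import numpy as np

from cryolig import (
    DensityMap,
    fsc_curve,
    make_toy_transporter,
    resolution_at,
    simulate_map,
    SimulationParams,
)

model = make_toy_transporter(60.0, seed=2)
params = SimulationParams(resolution=5.0, voxel_size=1.043)
signal = simulate_map(model, params)

halves = []
for seed in (10, 20):
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 0.10 * signal.values.max(), signal.dims)
    halves.append(DensityMap(signal.values + noise, signal.voxel_size, signal.origin))

curve = fsc_curve(halves[0], halves[1])
res = resolution_at(curve, criterion=0.143)

print(f"shells                    : {len(curve.fsc)}")
print(f"FSC in the lowest shell   : {curve.fsc[0]:.3f}")
print(f"resolution (FSC = 0.143)  : {res.resolution:.2f} Å"
      + ("  (Nyquist-limited)" if res.nyquist_limited else ""))
print()
print("Identical signal with independent noise correlates strongly at low")
print("frequency and decorrelates where noise overtakes signal; the 0.143")
print("crossing is the conventional global-resolution estimate.")
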