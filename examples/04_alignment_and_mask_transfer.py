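"""Transfer CT-defined organ masks to the PET grid; recover a known rigid shift.

Mask transfer resamples the CT-grid label volume onto the coarser PET
lattice with nearest-neighbor sampling; the dice against a direct PET-grid
rasterization quantifies the discretization cost. Registration maximizes
mutual information with a one-plus-one evolutionary optimizer (initial
radius 0.009, epsilon 1.5e-4, up to 1000 iterations).
"""

import numpy as np

from petquant.phantom import desk_phantom_spec, generate_phantom
from petquant.spatial import dice, register_rigid, resample_mask

phantom = generate_phantom(desk_phantom_spec(noise_sd=50.0, seed=1))

print("CT -> PET mask transfer (dice vs direct PET rasterization):")
for name in ("breast_r", "liver", "spleen"):
    moved = resample_mask(phantom.ct_masks[name], phantom.pet_raw.grid)
    print(f"  {name:<10} dice {dice(moved, phantom.masks[name]):.4f}")

shift = (6.0, -4.0, 3.0)
moving = generate_phantom(desk_phantom_spec(noise_sd=50.0, seed=2, shift_mm=shift)).ct
result = register_rigid(phantom.ct, moving)
recovered = np.asarray(result.transform.translation)
print(f"\napplied shift (mm):   {shift}")
print(f"recovered shift (mm): {np.round(recovered, 2).tolist()}")
print(f"max error {np.abs(recovered - shift).max():.2f} mm "
      f"(half a PET voxel is 2.4 mm); converged={result.converged}")
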