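"""Estimate the susceptibility displacement field from an AP/PA pair.

The estimator aligns the opposite-polarity b0 images by minimising the
Jacobian-modulated mid-way mismatch in a coarse-to-fine schedule of Gaussian
kernels, and the result is compared against the phantom's known field.
"""

import numpy as np

from rpgdwi import ProtocolConfig, estimate_displacement, make_phantom, simulate_acquisition
from rpgdwi.unwarp import UnwarpParams

cfg = ProtocolConfig(n_stations=2)
truth = make_phantom(cfg, seed=1)
stations = simulate_acquisition(truth, cfg, seed=1)
ap, pa = stations[0], stations[1]  # station 0, both polarities

# coarse schedule (2 mm kernel decrements) for a quick demonstration;
# the default is 0.25 mm decrements as used for real data
params = UnwarpParams(fwhm_step_mm=2.0)
field, trace = estimate_displacement(ap.volumes[0.0], pa.volumes[0.0], params, return_trace=True)

pe_sp = cfg.spacing[cfg.pe_axis]
d_true = truth.crop(truth.true_displacement(0).d, 0)
body = truth.crop(truth.body_mask, 0)
rmse = np.sqrt(np.mean(((field.d - d_true)[body] / pe_sp) ** 2))

print(f"levels: {len(trace)} (FWHM {trace[0]['fwhm_mm']} -> {trace[-1]['fwhm_mm']:.2f} mm)")
for lv in (trace[0], trace[-1]):
    drop = 100 * (1 - lv["costs"][-1] / lv["costs"][0])
    print(f"  level FWHM {lv['fwhm_mm']:5.2f} mm: cost {lv['costs'][0]:.3e} -> "
          f"{lv['costs'][-1]:.3e} ({drop:.1f}% drop; grids differ between levels)")
print(f"true field range: [{d_true.min() / pe_sp:.2f}, {d_true.max() / pe_sp:.2f}] voxels")
print(f"estimated field RMSE inside body: {rmse:.3f} voxels")
print("(< 0.5 voxel means the correction is sub-voxel accurate)")
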