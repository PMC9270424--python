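"""Correct a whole b-value series and fit ADC maps.

The field estimated from the b0 AP/PA pair corrects every b-value of the
station (susceptibility distortion is independent of b), then ADC is fitted
voxel-wise from b50/b400/b900 by the log-linear least-squares mono-
exponential model.  ADC values barely change with correction — the
correction moves signal, it does not re-weight the decay.
"""

import numpy as np

from rpgdwi import ProtocolConfig, correct_station, fit_adc, make_phantom, simulate_acquisition
from rpgdwi.unwarp import UnwarpParams

cfg = ProtocolConfig(n_stations=2)
truth = make_phantom(cfg, seed=1)
stations = simulate_acquisition(truth, cfg, seed=1)
ap, pa = stations[0], stations[1]

corrected = correct_station(ap, pa, UnwarpParams(fwhm_step_mm=2.0), reference_b=0.0)

adc_nc = fit_adc(ap.volumes)          # non-corrected
adc_dc = fit_adc(corrected.volumes)   # distortion corrected

labels = truth.crop(truth.labels, 0)
print(f"{'tissue':>16s} {'true ADC':>9s} {'NC':>7s} {'DC':>7s}   (1e-3 mm^2/s)")
for lab, name in sorted(truth.label_names.items()):
    roi = labels == lab
    if lab < 1 or roi.sum() < 30:
        continue
    true_adc = truth.crop(truth.adc, 0)[roi].mean()
    print(
        f"{name:>16s} {true_adc:9.3f} {adc_nc.adc.data[roi].mean():7.3f}"
        f" {adc_dc.adc.data[roi].mean():7.3f}"
    )
print("\nWhere distortion is small, NC and DC agree and both track the truth.")
print("The kidney sits inside a field bump: its distorted-image ROI mean is")
print("biased, and correction moves it back toward the ground-truth value.")
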