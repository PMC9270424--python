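# rpgdwi

Reverse-polarity-gradient (RPG) susceptibility-distortion correction for
multi-station whole-body diffusion-weighted MRI (WB-DWI), with a synthetic
ground-truth phantom and a quantitative geometric-accuracy evaluation suite.

## The problem

Whole-body DWI is acquired with single-shot EPI, whose low bandwidth along
the phase-encode (PE) axis turns static field inhomogeneity Δf(x) into a
geometric displacement

    d(x) = Δf(x) / bw_pp · Δp        [mm]

along the PE axis (`bw_pp` = PE pixel bandwidth, `Δp` = PE pixel size).
DWI and the structural images acquired in the same session are therefore not
aligned, which hampers lesion detection, segmentation and quantitative ADC
analysis. Two EPI acquisitions with opposite PE gradient polarity (AP / PA)
are displaced in *exactly opposite* directions, so the undistorted image
lies mid-way between them — that is what the RPG method exploits.

## The method

Given an AP/PA image pair, `rpgdwi` estimates the voxel-wise PE displacement
field d by minimising, within a coarse-to-fine schedule of Gaussian
smoothing kernels,

    C(d) = Σₓ [ I_AP(x + d(x)) (1 + d′(x)) − I_PA(x − d(x)) (1 − d′(x)) ]²
           + λ₁ Σ‖∇d‖² + λ₂ Σ‖∇²d‖²

where d′ is the PE derivative of d and the (1 ± d′) factors are the
Jacobians that undo signal pile-up in compressed regions. Defaults follow
the published protocol: λ₁ = 0, λ₂ = 1000 (images rescaled to a common
~[0, 1000] intensity range), kernels from 16 mm down to native resolution in
0.25 mm steps, 5 optimisation iterations per level. Because susceptibility
distortion does not depend on the diffusion weighting, the field estimated
from the b0 (or b50) pair corrects **all** b-values of the series via
`corrected(x) = distorted(x + d(x)) · max(0, 1 + d′(x))`.

Around the estimator the package provides the full WB-DWI workflow:

| stage | module | what it does |
| --- | --- | --- |
| phantom | `rpgdwi.phantom` | multi-station AP/PA acquisition with known S0/ADC/field ground truth, Rician noise, station offsets/scales, lesions |
| correction | `rpgdwi.unwarp` | field estimation, Jacobian-modulated correction of whole b-value series, station-wise datasets |
| quantification | `rpgdwi.pipeline` | mono-exponential log-linear ADC fit (b50/b400/b900), overlap removal and whole-body assembly, histogram matching of overlap slices |
| evaluation | `rpgdwi.evaluation` | mutual information vs structural reference, Dice / centroid distance / average Hausdorff on ROIs, Bland–Altman, paired Wilcoxon signed-rank |
| I/O + CLI | `rpgdwi.io`, `rpgdwi.cli` | NIfTI-1 volumes with JSON sidecars (PE axis/polarity), dataset manifests, YAML-configured end-to-end runs |

## Worked example

Estimate the displacement field of a simulated station and compare it with
the phantom's ground truth (`examples/02_estimate_field.py`):

```python
from rpgdwi import ProtocolConfig, estimate_displacement, make_phantom, simulate_acquisition
from rpgdwi.unwarp import UnwarpParams

cfg = ProtocolConfig(n_stations=2)
truth = make_phantom(cfg, seed=1)
stations = simulate_acquisition(truth, cfg, seed=1)
ap, pa = stations[0], stations[1]

params = UnwarpParams(fwhm_step_mm=2.0)   # quick demo schedule
field = estimate_displacement(ap.volumes[0.0], pa.volumes[0.0], params)
```

prints

```
levels: 8 (FWHM 16.0 -> 3.40 mm)
  level FWHM 16.00 mm: cost 8.891e+07 -> 6.245e+07 (29.8% drop; grids differ between levels)
  level FWHM  3.40 mm: cost 2.063e+08 -> 2.021e+08 (2.0% drop; grids differ between levels)
true field range: [-4.11, 0.26] voxels
estimated field RMSE inside body: 0.296 voxels
(< 0.5 voxel means the correction is sub-voxel accurate)
```

The phantom's field displaces tissue by up to ~4 voxels in this station; the
estimate recovers it with ~0.3 voxel RMS error, i.e. the corrected image is
geometrically sub-voxel accurate. The other scripts in `examples/` walk
through phantom construction, whole-series correction + ADC fitting,
whole-body assembly with histogram matching, and the full evaluation report
(mutual information, lesion overlap metrics, paired tests).

The same stages are available from the shell:

```bash
rpgdwi simulate --seed 0 --out data/
rpgdwi unwarp --manifest data/manifest.json --reference-b 0 --out corrected/
rpgdwi adc --manifest data/manifest.json --out adc/
rpgdwi run-full --config config.yaml
```

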