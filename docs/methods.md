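# Methods

## Distortion model

EPI susceptibility distortion is modelled geometrically: off-resonance
Δf(x) (Hz) displaces signal along the phase-encode (PE) axis by
d(x) = Δf(x)/bw_pp · Δp millimetres, where bw_pp is the PE pixel bandwidth
and Δp the PE pixel size. The displacement is identical for every b-value
of a scan session and exactly opposite between AP and PA polarity. The
forward operator is a conservative one-dimensional pushforward: the
intensity of each source voxel is split between the two nearest target
voxels along the PE line with linear ("cloud-in-cell") weights. This is the
discrete adjoint of linear interpolation; it conserves each PE line's total
signal exactly (up to signal pushed outside the grid, which is dropped, as
signal leaving the field of view is in reality) and reproduces signal
pile-up where the field compresses space. No k-space effects (T2* blur,
ghosting), eddy-current distortion or motion are modelled.

The inverse operator samples the distorted image at x + sign·d(x) with
linear interpolation and multiplies by the Jacobian 1 + sign·∂d/∂p
(central differences in the interior, one-sided at the boundary), floored at
zero so fold-over produces no signal rather than negative signal.

Coordinates are 0-based and voxel-centred; displacement fields are stored in
mm as functions of the *undistorted* position, with positive values pointing
toward increasing PE index for AP polarity.

## Field estimation

The displacement field is estimated from an AP/PA image pair by minimising

    C(d) = Σₓ [ Ĩ_AP(x+d)(1+d′) − Ĩ_PA(x−d)(1−d′) ]²
           + λ₁ Σ‖∇d‖² + λ₂ Σ‖∇²d‖²

per smoothing level, where Ĩ are the level-smoothed images, d′ is the PE
derivative of d in voxel units, λ₁ weights squared first differences and λ₂
squared second differences (a discrete bending energy) over all three axes.
The regularised problem is well-posed with λ₁ = 0 because λ₂ > 0 penalises
curvature along every axis.

Defaults (units matter: both images are first rescaled so their 99.9th
intensity percentile is 1000, making one λ setting valid across scanners
and stations):

| parameter | default | meaning |
| --- | --- | --- |
| λ₁ | 0 | first-order smoothness weight |
| λ₂ | 1000 | bending-energy weight |
| fwhm_start_mm | 16 | coarsest Gaussian kernel |
| fwhm_step_mm | 0.25 | kernel decrement per level |
| fwhm_stop | native | finest kernel = largest in-plane voxel size |
| iters_per_level | 5 | descent iterations per level |
| step_size | 1.0 voxel | cap on the per-iteration field update |
| combine_mode | ap_only | correct AP only; "average" combines corrected AP and PA |

Optimisation is first-order descent with an analytic gradient, a diagonal
Gauss–Newton preconditioner and a backtracking line search, so the cost is
non-increasing within every level. The preconditioner sums the squared
translation sensitivity 2(∂Ĩ_AP(1+d′) + ∂Ĩ_PA(1−d′))², the pile-up
sensitivity ½(Ĩ_AP+Ĩ_PA)², and the regulariser stencil diagonals (12λ₁ +
36λ₂); plain unpreconditioned descent was measurably slower to converge in
deep pile-up regions where the image-gradient term vanishes at the ridge
apex. Each level additionally registers on a grid decimated per axis to
⌊FWHM/(2·spacing)⌋ (capped at 4): an image smoothed to FWHM w carries no
information below ~w/2 sampling, the coarse levels become ~4× cheaper, and
one coarse-grid step moves the field by several native voxels, which is
where the capture range for 6-voxel displacements comes from. The field is
warm-started across levels (resampled when the grid changes), initialised to
zero at the coarsest level, and constrained to zero outside a loose body
mask (smoothed AP+PA mean above 5% of its robust maximum, dilated).

The estimation is fully 3D with the displacement constrained to the PE axis.
The field estimated at the reference b-value (0 by default, 50 as the
perfusion-insensitive clinical alternative) is reused unchanged for every
b-value of the station; stations are corrected independently.

A coarse schedule (`fwhm_step_mm=2.0`, eight levels instead of ~51) is used
by the test-suite and demo scripts; it is *not* the default. Measured
ground-truth recovery on the standard phantom (five stations, max |d| ≈ 6
voxels, SNR ≈ 30): 0.04–0.12 voxel RMSE per station with the default
schedule, 0.08–0.45 with the coarse one — both sub-voxel, and the
test suite verifies the coarse numbers on every run.

## ADC and assembly

ADC is fitted voxel-wise by ordinary least squares of ln S(b) on b over
b = 50/400/900 s/mm² (the mono-exponential model S = S0·e^(−b·ADC); ADC
reported in 10⁻³ mm²/s). Voxels with any non-positive signal among the
fitted b-values are flagged invalid and set to 0; negative slopes on valid
voxels are reported unclamped. The fit is exact (to machine precision) on
noiseless exponentials for any ≥ 2 b-values.

Whole-body volumes are assembled by removing overlapping slices — an equal
number from each adjacent station, ⌈n/2⌉ trailing from the superior and
⌊n/2⌋ leading from the inferior station when n is odd (the tie-break is a
documented choice) — and concatenating without intensity blending. For
display volumes only, inter-station intensity differences are harmonised by
histogram matching of the overlap slices, chained superior → inferior: each
station's overlap CDF is mapped onto the already-matched neighbour's overlap
CDF via linear interpolation between 256 empirical quantile knots, a
monotone mapping applied to the whole station.

## Evaluation metrics

* **Mutual information** between a low-b volume and the structural
  reference (resampled to the DWI grid), from a 64-bin equal-width joint
  histogram in natural-log units, computed over the full station volume.
  Bin count, log base and masking are implementation choices — absolute MI
  values are comparable only within this package; orderings (corrected vs
  not) are the meaningful output.
* **DSC / ED / AVD** between an image-derived lesion segmentation and the
  ground-truth mask: Dice coefficient, Euclidean distance of unweighted
  voxel-centre centroids (mm), and average Hausdorff distance — the
  symmetric mean nearest-surface distance over face-connectivity boundary
  voxels (mm). Image-side segmentations stand in for manual outlining via
  Otsu's threshold inside a dilated neighbourhood of the true mask.
* **Bland–Altman** bias and 1.96·SD limits of agreement (sample SD) of
  paired differences, and **paired two-sided Wilcoxon signed-rank tests**:
  zero differences dropped, mid-ranks for ties, W = min(W⁺, W⁻), exact
  p by full 2ⁿ enumeration for n ≤ 12 without ties, otherwise a normal
  approximation with tie-corrected variance and 0.5 continuity correction.

## The phantom

The synthetic phantom emulates the structure the correction relies on, not
anatomy. On a 96×96×84 grid at 3.4×3.4×6 mm (five stations × 20 slices,
4 overlapping slices; in-plane spacing from a 440 mm field of view at a
128 matrix, the protocol scale the defaults mirror):

* an elliptical body cylinder of soft tissue (S0 600 a.u., ADC 1.2) with a
  posterior spine column and seven seeded ellipsoidal organs spanning the
  physiological contrast range (bladder ADC 3.0 down to bone 0.45);
* an off-resonance field = low-order polynomial background (≤ ~1 Hz) +
  two fixed Gaussian bumps at "air cavity" sites in the neck and abdomen
  (+120/−90 Hz, σ ≈ 25 mm) + per-station constant central-frequency offsets
  drawn uniformly from ±4 Hz. At the phantom's PE pixel bandwidth of
  20 Hz/px this yields a maximum displacement of ~6 voxels at the bumps,
  ≤ 0.2 voxel bulk shifts between stations, and guarantees both strongly
  distorted (≥ 2 voxel) and quasi-undistorted (< 0.25 voxel) regions — the
  two regimes whose contrast the evaluation demonstrates. The PE bandwidth
  is a free model parameter: clinical protocols do not usually report it,
  and only the product Δf/bw_pp matters to the geometry;
* acquisition per station, polarity and b ∈ {0, 50, 400, 900} s/mm²:
  mono-exponential signal, conservative pushforward with the station's
  field (opposite sign for PA), per-station intensity scale (±8%), Rician
  noise (two Gaussian quadratures, magnitude) with σ = noise_sigma/√NSA and
  NSA = 2/2/4/9. The default noise_sigma = 20 gives SNR ≈ 30 against the
  median in-body b0 signal;
* a structural reference = the undistorted, noiseless b0 contrast on a
  finer in-plane grid (standing in for a same-session anatomical scan:
  geometric evaluation needs an undistorted reference, not realistic
  T1 contrast);
* optional spherical lesions (default radius 14 mm, bright S0 1200, ADC
  2.5) overwriting the maps where embedded, with their masks recorded.

What the phantom does **not** emulate — and hence what passing tests do not
show about real data: anthropomorphic anatomy, breathing motion,
fat-suppression physics, fold-over/aliasing, eddy-current distortion,
T2*/ghosting artefacts, and the registration artefacts real inhomogeneous
tissue can induce. Ground-truth recovery here bounds the method's geometric
accuracy under its own model assumptions only.

## Degenerate inputs and numerical choices

* Jacobian factors are floored at 0; out-of-grid pushforward signal is
  dropped and reported as a fraction on request.
* Gaussian smoothing uses reflective boundaries (mean-preserving) and a
  6σ kernel support; FWHM 0 is the identity.
* Resampling is trilinear on voxel-centred coordinates with nearest-edge
  extrapolation.
* `rescale_intensity` refuses all-zero volumes; MI of a constant image is
  0 with a warning; Dice of two empty masks, surface distances of empty
  masks and histogram matching without overlap are errors; an all-zero
  difference vector gives Wilcoxon p = 1 with a warning.
* All randomness flows from explicit seeds through
  `numpy.random.SeedSequence` spawning (one independent stream per station,
  polarity and b-value); repeated runs are bit-identical.

## Known limitations

* The estimator recovers smooth fields; a discontinuous field (metal
  implant) violates the bending-energy prior.
* In fold-over regions (|d′| ≥ 1) signal is irrecoverably collapsed; the
  Jacobian floor prevents artefacts but cannot restore information.
* The average combine mode assumes both polarities exist for each b-value
  and falls back to AP with a warning otherwise.
* MI values depend on the 64-bin histogram choice and are not comparable
  with other implementations.
* The coarse test schedule trades ~3× field-recovery accuracy for ~7×
  speed; quantitative use should keep the default schedule.
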