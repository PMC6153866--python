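# Methods

This note documents the models behind `lppvc`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical choices a user should know before trusting a number.

## Acquisition model

The simulator is a stack-of-slices idealization of a clinical PET ring.
Expected data for an activity image `x` (kBq/mL) are

```
λ = n · a · c · Ray(G x) + s
```

* `G` — isotropic, shift-invariant Gaussian point-spread function applied
  in image space. Real scanners have a spatially variant PSF; the uniform
  approximation is adequate near the transaxial center (where carotid and
  aortic structures sit) and degrades towards the FOV edge. The FWHM is a
  free parameter: 4 mm emulates a resolution-modeled chain, 8 mm an
  unmodeled OSEM chain.
* `Ray` — 2D parallel-beam line integrals per axial slice, views uniformly
  spaced over 180°. The projector is materialized once per geometry as a
  sparse matrix of sampled line integrals (bilinear interpolation at
  half-voxel steps along each ray, weights in mm); its transpose is the
  exact adjoint, which the EM reconstruction requires. Defaults: 120 views,
  radial bin = transaxial voxel (2.03 mm). Real scanners measure fully-3D
  oblique LORs; the slice-wise geometry preserves everything the LP model
  needs (a linear projection operator with per-bin attenuation and additive
  scatter) at desk scale.
* `a` — attenuation survival factors `exp(−∫ μ dl)` computed from the μ-map
  with the same ray transform (no PSF).
* `s` — additive scatter. Full single-scatter simulation is out of scope;
  the surrogate smooths the unscattered trues with a wide (80-mm FWHM)
  Gaussian along the radial and axial axes and rescales so scatter makes up
  the declared fraction (default SF = 0.2) of all events. This reproduces
  the contract the correction relies on — a smooth, known, additive term —
  but not the object-specific shape of real scatter tails.
* `n` — normalization (default all-ones), `c` — count scale, expressed as
  total detected counts per kBq/mL·mm³ summed over views. `c` is usually
  calibrated so the expected sinogram total hits a target count level;
  10⁶ counts is the default reference level (comparable to a short clinical
  bed at these activities), and the thorax study driver uses 5×10⁶ to
  reflect that phantom's five-fold longer listed acquisition.
* Counting noise — independent Poisson per bin, single integer seed per
  simulation.

Randomness: every stochastic stage takes one integer seed; fixed seeds give
bit-identical sinograms.

## Phantoms

Phantoms are declarative (grid, voxel size, body primitives, lesion list)
and rasterized deterministically.

* **Image-quality phantom** — six fillable spheres (10, 13, 17, 22, 28,
  37 mm inner diameter) on a 57.2-mm-radius ring inside a water cylinder;
  background 4.8 kBq/mL, sphere:background ratio 4.95. Default grid
  128×128×48 at 2.03-mm isotropic voxels — a desk-scale stand-in for the
  336-wide clinical matrices; grid and ring are spec fields.
* **Thorax phantom** — elliptic body (semi-axes 110×80 mm) with two
  low-density lung compartments and three spherical "plaque-type" lesions
  of 36, 31 and 18 mm³ at 70:1 over a 4.0 kBq/mL background. The lesion
  positions are not anatomically prescribed; the defaults sit in the
  mediastinal soft tissue between the lungs and are configurable fields.
* **Carotid section** — a soft-tissue neck cylinder with a vessel, one
  plaque lesion of configurable volume (the patient range is roughly
  50–500 mm³) and HU (driving the four-class calcification taxonomy), and
  an arterial reference segment 10–15 mm below the plaque for the
  background mean.

Sub-voxel lesions (all three thorax lesions: 3.25–4.1 mm diameter vs
2.03-mm voxels) are represented by fractional occupancy times intended
activity, which conserves activity mass; the voxelized maximum is then
attenuated by occupancy, so the builders also emit the *intended*
(pre-rasterization) activities as the ground-truth (EXP) reference.
Occupancy is estimated by sub-voxel sampling (8³ points per voxel, 16³ for
sub-voxel lesions; ~1% mass accuracy). Attenuation uses a two-compartment
default (water 0.0096 mm⁻¹, bone/calcification 0.017 mm⁻¹, lung
0.0026 mm⁻¹ at 511 keV); HU is stored as a separate volume, not converted
to μ.

## Reconstruction

OSEM with the standard update over round-robin angle subsets,
attenuation/normalization as multiplicative and scatter as additive terms.
Defaults 5 iterations × 21 subsets; when the subset count does not divide
the view count, subsets differ by one view. `psf_in_recon` puts the
Gaussian blur inside the reconstruction operator (resolution modeling);
reconstructing blurred data without it yields the familiar
resolution-limited image, with it the sharper — and Gibbs-prone — one.
Numerical guards: denominators floored at 1e−10; voxels whose subset
sensitivity falls below 1e−8 of the maximum are frozen at zero (outside the
sampled FOV). The initial image is a uniform constant scaled so the model
total matches the measured total. A 5-mm Gaussian post-filter replicates
the clinical processing of the unmodeled OSEM arm.

## The LP fit

* **Support** — the fit uses only bins where the summed tissue projections
  are non-zero (rays that see the VOI), keeping the problem local.
* **VOI** — the segmented lesion dilated by a metric margin (default 12 mm,
  ≈1.5× the widest PSF used); the shell is the local-background tissue,
  optional extra masks become further compartments. A VOI touching the grid
  boundary is rejected.
* **Weights** — inverse-variance weights for Poisson counts, taken from the
  model expectation: `w_i = 1/max(g_out,i + Σ_j A_j P_ij, 1)`, iterated
  twice from an initial `w_i = 1/max(g_out,i, 1)`. Weighting by the
  *observed* counts is the textbook high-count shortcut but fails at
  clinical plaque count densities (roughly one count per bin): the weights
  then anti-correlate with the noise and drag the non-negative fit towards
  zero. Model-based weights keep the estimator unbiased at any count level;
  with noise-free data the recovery is exact regardless of weights.
* **Non-negativity** — on by default (activities are concentrations),
  solved by NNLS; the unconstrained path exists for diagnostics. Reported
  alongside: residual norm and the Fisher covariance `(MᵀWM)⁻¹`.
* **Degeneracy** — tissue projections with cosine similarity above 0.999 on
  the support abort the fit ("degenerate tissue projections") instead of
  returning an ill-conditioned estimate.
* **g_out** — projection of the reconstructed image with the VOI zeroed,
  plus the scatter estimate. The outside image is projected with the
  *residual* blur between the model PSF and the resolution the image
  already carries: an unmodeled OSEM image is already at system resolution,
  so re-applying the full PSF would double-blur and bias the fitted lesion
  activity low (measured: ~1.5% on a 37-mm sphere, and ~+0.9 mm on the PSF
  calibration). For resolution-recovered images the full blur applies.
* **PSF calibration** — bounded scalar search (tolerance 0.1 mm) for the
  FWHM that makes the LP ratio of a large (≥30 mm) known sphere match its
  true ratio; an optimum at a search bound raises an error. Self-consistency
  on noise-free simulations recovers 4.0 and 8.0 mm within ±0.35 mm.

The full pipeline (`run_lp_pvc`) chains segmentation (CT threshold with
largest-connected-component, PET half-max adapted to background, or a given
mask) → VOI → projections and g_out → fit → substitution → noisy or
noise-free re-simulation with full physics → OSEM. Each stage failure is
tagged with its stage name. The substituted image is bit-identical to the
input outside the VOI; the re-reconstructed PVC image is, of course, a new
image everywhere.

A rigid integer-voxel shift utility supports synthetic misregistration
experiments; registration itself is out of scope.

## Quantification

Background means come from ≥3 spherical VOIs (default 15-mm diameter)
placed deterministically in uniform body regions — at a moderate target
depth (25 mm), because the deepest regions of an attenuating body are where
low-count reconstructions are noisiest and biased. LBR_A50 follows the
half-max-adapted-to-background isocontour connected to the maximum.
ΔLBR is the exact relative-change formula, sign preserved. The hyperbolic
trend `y = A/x + B` is fitted by ordinary least squares in `1/x` (the
reference analysis states no weighting); parameter standard errors come
from the linear regression. The one-sided paired t-test defaults to the
alternative "corrected exceeds uncorrected"; identical pairs return
t = 0, p = 0.5 by convention, zero-variance inputs are rejected.

## Study drivers and problem sizes

The bundled studies run at 128×128×48 / 120 views (the "desk" scale, a few
seconds per simulation and reconstruction on one core); the test suite uses
64×64×16 / 60 views ("tiny") throughout. Choices made for the drivers:

* The image-quality recovery study reports LP ratios over the *known* fill
  background (the well-counter-style reference) rather than the measured
  image background, because at ~10⁶ counts the reconstructed background
  estimate carries 8–20% low-count bias that would otherwise dominate a
  deviation metric aimed at the fit itself.
* At that count level the fitted activity of the 17-mm sphere has ~7%
  relative standard deviation — at the Fisher information bound, confirmed
  against the reported covariance — so the maximum-deviation statistic over
  the 17–37 mm spheres genuinely fluctuates between ~2% and ~16% across
  seeds while the noise-free pipeline recovers all spheres within ~1%.
* The thorax ΔLBR study follows the unmodeled-OSEM chain (8-mm acquisition
  PSF, 5-mm post-filter, half-max PET segmentation). Under this composition
  the image chain is ~10 mm effective; the half-max masks of sub-voxel
  lesions then cover several hundred mm³, which caps the achievable
  ΔLBR_max at roughly 60–150% across seeds (the cap is structural: it
  persists in the high-count limit). Sharper chains yield substantially
  larger gains, and the gains quoted for physical-phantom measurements at
  ~7-mm effective resolution are consistent with that.
* The lesion-size sweep uses supra-voxel volumes (60–3000 mm³): above the
  sampling limit the correction gain falls monotonically with volume
  (Spearman ≈ −0.94); below ~3 voxels per axis the trend reverses because
  half-max segmentation dilutes the fitted activity — the sub-voxel caveat,
  asserted separately (the LP ratio of an 18-mm³ lesion with PET-based
  segmentation stays below the true 70:1).

## Known limitations

* Shift-invariant PSF, 2D slice geometry, no randoms, decay or dead time;
  normalization defaults to uniform.
* The scatter surrogate has the right magnitude and smoothness but not the
  object-specific shape of single-scatter tails, and the simulation and
  correction share the same scatter estimate (no scatter-model mismatch is
  exercised).
* Phantoms are piecewise-constant; real tissue textures, motion and
  PET–CT misregistration are not emulated (a voxel-shift utility allows
  constructing the latter synthetically).
* Passing tests on these synthetic conditions demonstrates correctness of
  the algorithms and their stated statistical behavior, not clinical
  performance on scanner data.
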