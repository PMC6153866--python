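# lppvc — local-projection partial-volume correction for PET

Small hot lesions — the atherosclerotic plaques imaged with ¹⁸F-NaF PET/CT
being the motivating case — are comparable in size to the scanner's point
spread function. The resulting partial-volume effect (PVE) spills their
activity into the surroundings and can suppress a plaque's apparent uptake
several-fold, which confounds any lesion-to-background quantification.

`lppvc` implements the **local-projection (LP) partial-volume correction**
together with everything needed to evaluate it end-to-end on synthetic data:
digital phantoms, an analytic PET acquisition simulator, OSEM
reconstruction with optional resolution modeling, segmentation rules, and
the quantification/statistics layer. It is aimed at researchers studying
quantitative PET of small lesions who want a compact, fully inspectable
desk-scale pipeline.

## The method

Consider J segmented tissue compartments (the lesion of interest plus its
local background, optionally more) inside a small volume of interest (VOI).
The expected counts in every sinogram bin *i* whose ray crosses the VOI are
modeled as

```
λ_i = Σ_j A_j · P_ij + g_out,i
```

where `P_ij` is the resolution-blurred, attenuated, normalized projection
of tissue *j*'s indicator at unit activity, `A_j` the unknown tissue
activity concentration (kBq/mL), and `g_out,i` the counts originating
outside the VOI (estimated by projecting the reconstructed image with the
VOI zeroed, plus the scatter estimate). The `A_j` are obtained by weighted
least squares against the measured projections (inverse-variance weights
from the model expectation, non-negativity enforced). Substituting the
`A_j` into the VOI, forward-projecting with full physics and reconstructing
once more yields the partial-volume-corrected (PVC) image.

Quantification uses the lesion-to-background ratio `LBR = lesion statistic
/ background mean` (max voxel, mask mean, or the mean inside the half-max
isocontour adapted to background, `LBR_A50`) and the correction gain

```
ΔLBR (%) = (LBR_PVC − LBR_noPVC) / LBR_noPVC × 100 .
```

Plaques are classified by maximum CT density: non-calcified (< 110 HU),
light (110–210), medium (210–550), heavy (≥ 550); trends of LBR/ΔLBR
against volume or density are summarized by the hyperbolic fit
`y = A/x + B` with Pearson/Spearman correlations and a one-sided paired
t-test.

## Worked example

```pycon
>>> import lppvc
>>> from lppvc.presets import nema_spec
>>> ph = lppvc.build_nema_iq(nema_spec("desk"))          # six hot spheres, 4.95:1
>>> sim = lppvc.simulate_acquisition(ph.activity, ph.mu, psf_fwhm_mm=8.0,
...     scatter_fraction=0.2, target_total_counts=2e7, n_angles=120, noise=False)
>>> img = lppvc.osem(sim.counts, sim.model, lppvc.ReconConfig(5, 21))
>>> res = lppvc.run_lp_pvc(sim.counts, img, sim.model,
...     lesion_mask=ph.lesion_mask(2), margin_mm=12.0, noise=False)
>>> res.lp_fit.activities
array([22.79, 5.29])
```

This is `examples/03_lp_pvc_pipeline.py`; it prints

```
LP tissue activities: lesion 22.79, local background 5.29 kBq/mL
  (truth: 23.76 and 4.80 kBq/mL)
LBR_max: OSEM image 3.65, PVC image 3.57, LP activity ratio 4.75, EXP 4.95
```

Reading: at 8-mm resolution the 13-mm sphere's maximum-voxel ratio drops
from the true 4.95 to 3.65; the LP fit recovers the lesion activity to
within ~4% (ratio 4.75). The re-reconstructed PVC image passes through the
resolution-limited system again, so the directly fitted activities are the
most accurate reading — the behavior the method is designed around.

The other scripts in `examples/` cover phantom construction, simulation and
reconstruction arms, PSF self-calibration from a 37-mm sphere, and the
plaque-style quantification sweep (each prints its own interpretation).

A thin CLI mirrors the pipeline stages
(`lppvc phantom | simulate | recon | pvc | quantify | calibrate`); run
`lppvc --help`.

## Package layout

| module | contents |
| --- | --- |
| `lppvc.phantoms` | declarative phantom specs, sphere rasterization, NEMA-IQ / thorax / carotid builders |
| `lppvc.system_model` | Gaussian PSF + parallel-beam projector, attenuation, scatter surrogate, Poisson noise |
| `lppvc.recon` | OSEM (additive scatter / multiplicative attenuation), resolution modeling, post-filter |
| `lppvc.lp` | segmentation, local VOI, tissue projections, the LP fit, substitution, full PVC pipeline, PSF calibration |
| `lppvc.quantify` | LBR variants, ΔLBR, plaque classes, hyperbolic fits, association statistics, experiment tables |
| `lppvc.studies` | end-to-end study drivers (image-quality recovery, thorax ΔLBR, lesion-size sweep) |
| `lppvc.io` / `lppvc.cli` / `lppvc.presets` | NIfTI + npz + YAML formats, the CLI, tiny/desk presets |

Methodological details, parameter defaults and known limitations are
documented in [`docs/methods.md`](docs/methods.md).
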