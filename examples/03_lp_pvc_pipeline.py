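"""Full local-projection partial-volume correction of one sphere.

The LP method segments the lesion and a local background shell inside a
small VOI, computes each tissue's unit-activity projection under the full
physics model (PSF, attenuation, normalization), and fits the tissue
activities directly to the measured projection counts:

    lambda_i = sum_j A_j P_ij + g_out,i

The fitted activities replace the VOI voxels, the image is re-projected
with full physics and reconstructed again, yielding the PVC image.
Run on the 13-mm sphere of the image-quality phantom under an 8-mm
resolution chain (noise-free, so the remaining error is purely the
partial-volume effect).  Printed: fitted activities and the three ways of
reading the lesion-to-background ratio.
"""

import lppvc
from lppvc.presets import nema_spec

ph = lppvc.build_nema_iq(nema_spec("desk"))
sim = lppvc.simulate_acquisition(ph.activity, ph.mu, psf_fwhm_mm=8.0,
                                 scatter_fraction=0.2, target_total_counts=2e7,
                                 n_angles=120, noise=False)
img = lppvc.osem(sim.counts, sim.model, lppvc.ReconConfig(5, 21))

lid = 2  # the 13-mm sphere, strongly affected at 8-mm resolution
res = lppvc.run_lp_pvc(sim.counts, img, sim.model,
                       lesion_mask=ph.lesion_mask(lid), margin_mm=12.0,
                       noise=False)

bg = lppvc.background_voi_mask(ph.body_mask, [ph.lesion_mask(i) for i in ph.intended],
                               ph.activity.voxel_size_mm)
A = res.lp_fit.activities
print(f"LP tissue activities: lesion {A[0]:.2f}, local background {A[1]:.2f} kBq/mL")
print("  (truth: 23.76 and 4.80 kBq/mL)")
before = lppvc.lbr_max(img, ph.lesion_mask(lid), bg)
after = lppvc.lbr_max(res.pvc_image, ph.lesion_mask(lid), bg)
print(f"LBR_max: OSEM image {before:.2f}, PVC image {after:.2f}, "
      f"LP activity ratio {A[0] / ph.background_activity:.2f}, EXP 4.95")
print("the directly fitted LP ratio is the most accurate reading: the")
print("re-reconstructed PVC image passes through the resolution-limited")
print("system once more and loses part of the recovered contrast.")
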