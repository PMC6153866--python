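"""Simulate a PET acquisition of the image-quality phantom and reconstruct
it with OSEM, with and without resolution modeling.

The simulation blurs the activity with a 4-mm Gaussian point-spread
function, attenuates along each ray, adds a 20% scatter fraction and
draws Poisson counts.  The two reconstructions illustrate the resolution
trade: plain OSEM reproduces the blurred activity, while PSF-in-recon
(resolution modeling) recovers sharper spheres — at the price of Gibbs
overshoot at hot edges.  Printed: the maximum-voxel lesion-to-background
ratio per sphere against the true 4.95.
"""

import lppvc
from lppvc.presets import nema_spec

ph = lppvc.build_nema_iq(nema_spec("tiny"))
sim = lppvc.simulate_acquisition(ph.activity, ph.mu, psf_fwhm_mm=4.0,
                                 scatter_fraction=0.2, target_total_counts=2e7,
                                 n_angles=60, seed=42)
print(f"simulated {sim.counts.total:.0f} counts "
      f"(scatter fraction 0.20, PSF 4 mm, seed 42)")

osem_img = lppvc.osem(sim.counts, sim.model, lppvc.ReconConfig(5, 21))
psf_img = lppvc.osem(sim.counts, sim.model,
                     lppvc.ReconConfig(5, 21, psf_in_recon=True, psf_fwhm_mm=4.0))

bg = lppvc.background_voi_mask(ph.body_mask, [ph.lesion_mask(i) for i in ph.intended],
                               ph.activity.voxel_size_mm, diameter_mm=10.0,
                               clearance_mm=12.0, edge_clearance_mm=4.0,
                               target_depth_mm=15.0)
print(f"{'sphere':>8} {'OSEM':>6} {'PSF':>6} {'EXP':>6}")
for lid, m in sorted(ph.intended.items()):
    lo = lppvc.lbr_max(osem_img, ph.lesion_mask(lid), bg)
    lp = lppvc.lbr_max(psf_img, ph.lesion_mask(lid), bg)
    print(f"{m['diameter_mm']:6.0f} mm {lo:6.2f} {lp:6.2f} {4.95:6.2f}")
print("smaller spheres lose the most signal to the partial-volume effect;")
print("resolution modeling recovers part of it (and can overshoot).")
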