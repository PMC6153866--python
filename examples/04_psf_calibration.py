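"""Calibrate the effective system resolution from a large known sphere.

In practice the Gaussian PSF width of an imaging chain is not known
exactly.  It can be estimated by running the LP fit on a large sphere
(here 37 mm) with a known true activity ratio and searching the FWHM that
makes the fitted ratio match.  Printed: the recovered width against the
simulated truth for a sharp (4 mm) and a blurred (8 mm) chain.
"""

import lppvc

spec = lppvc.default_nema_spec(grid_shape=(96, 96, 36), diameters=(37.0,),
                               ring_radius_mm=0.0)
ph = lppvc.build_nema_iq(spec)
for true_fwhm in (4.0, 8.0):
    sim = lppvc.simulate_acquisition(ph.activity, ph.mu, psf_fwhm_mm=true_fwhm,
                                     scatter_fraction=0.2, target_total_counts=5e5,
                                     n_angles=60, noise=False)
    img = lppvc.osem(sim.counts, sim.model, lppvc.ReconConfig(5, 21))
    f = lppvc.calibrate_fwhm(sim.counts, img, sim.model, ph.lesion_mask(1),
                             true_ratio=4.95, background_mean=4.8, bounds=(1.5, 14.0))
    print(f"simulated FWHM {true_fwhm:.1f} mm -> calibrated {f:.2f} mm")
print("the recovered widths drive the tissue projections of the LP fit;")
print("a mismatched PSF biases the fitted lesion activity.")
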