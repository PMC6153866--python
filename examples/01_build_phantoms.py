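"""Build the three digital phantoms and inspect their ground truth.

Creates the image-quality phantom (six hot spheres at 4.95:1 over a
4.8 kBq/mL water background), the thorax phantom (three plaque-type
lesions of 36/31/18 mm^3 at 70:1) and a synthetic carotid section, then
prints the intended lesion activities and ratios.  The printed ratios are
the EXP reference values that the partial-volume correction tries to
recover from simulated scans.
"""

import lppvc
from lppvc.presets import nema_spec, thorax_spec

nema = lppvc.build_nema_iq(nema_spec("desk"))
print("Image-quality phantom: background %.1f kBq/mL" % nema.background_activity)
for lid, m in sorted(nema.intended.items()):
    print(f"  sphere {m['diameter_mm']:4.0f} mm: {m['activity']:.2f} kBq/mL "
          f"(ratio {m['activity'] / nema.background_activity:.2f})")

thorax = lppvc.build_thorax_plaque(thorax_spec("desk"))
print("\nThorax phantom: background %.1f kBq/mL, ground-truth ratio %.0f"
      % (thorax.background_activity, thorax.intended_lbr))
for lid, m in sorted(thorax.intended.items()):
    print(f"  lesion {m['volume_mm3']:4.0f} mm^3 (d = {m['diameter_mm']:.2f} mm, "
          f"below the 3-voxel sampling limit)")

carotid = lppvc.build_carotid_section(plaque_hu=600.0, plaque_volume_mm3=120.0)
hu_max = carotid.hu.values[carotid.lesion_mask(1)].max()
print(f"\nCarotid section: plaque HU {hu_max:.0f} -> class "
      f"'{lppvc.classify_plaque(hu_max)}'; reference segment "
      f"{int(carotid.reference_mask.sum())} voxels, 10-15 mm below the plaque")
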