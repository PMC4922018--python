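"""Serial-section volumetry of a synthetic kidney with dorsal-band damage.

Generates 5-um-thick labeled sections of an ellipsoidal haematopoietic
kidney whose blood cells are wiped out in a dorsal band (what a dorsal
heavy-ion beam does), with per-section alignment jitter.  The script
re-registers the stack, quantifies volume and blood-cell composition, and
splits the organ dorsally/ventrally and by beam field.
"""

import numpy as np

from fishbeam import morphometry3d as m3
from fishbeam import synthetic as syn

params = syn.SectionSimParams(
    depletion="dorsal-band", depletion_depth_um=160.0, depletion_factor=1.0,
    jitter_sd_px=2.0, seed=17,
)
stack, truth = syn.gen_section_stack(params)

alignment, aligned = m3.align_stack(stack)
applied = truth.applied_shifts.astype(float)
expected = -(applied - applied[alignment.reference_index])
good = [i for i in range(stack.n_sections) if i not in alignment.empty_sections]
rms = np.sqrt(((alignment.shifts[good] - expected[good]) ** 2).mean())
print(f"sections: {stack.n_sections}, registration shift error RMS: {rms:.2f} px")

H, W = params.grid_shape
band = (np.arange(H)[:, None] + 0.5) * params.pixel_size_um <= 160.0
field = np.broadcast_to(band, (H, W)).copy()
report = m3.volume_report(aligned, irradiated=field)

print(f"kidney volume  : {report.kidney_volume_um3:.3e} um^3 "
      f"(analytic ellipsoid {truth.analytic_volume_um3:.3e} um^3)")
print(f"blood fraction : total {report.blood_fraction:.3f} | "
      f"dorsal {report.dorsal_fraction:.3f} | ventral {report.ventral_fraction:.3f}")
print(f"beam field     : in-field {report.in_field_fraction:.3f} | "
      f"out-of-field {report.out_field_fraction:.3f}")
print("-> blood cells are absent exactly where the beam reached (in-field ~0,")
print("   out-of-field ~ the 0.25 baseline), the signature of a localized hit.")
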