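"""Dehydration statistics for one synthetic lesion.

Renders a SWIR and a thermal drying series for a partially-arrested lesion,
extracts the lesion/control ROI mean curves and prints ΔI and ΔQ with their
L−C and L/C contrasts.  Large ΔI/ΔQ contrasts mean a permeable, active
lesion; an arrested lesion would sit near the control values.
"""

import numpy as np

from cario import analyze_stack, synth

config = synth.CohortConfig(n_lesions=1, seed=42)
truth = synth.LesionTruth(
    lesion_depth_um=220.0,
    tsl_thickness_um=30.0,
    mineral_loss_frac=0.25,
    permeability=synth.permeability_from_tsl(30.0),
    surface_type="smooth",
    has_composite=True,
    water_pool_frac=0.0,
)
print(f"ground truth: TSL {truth.tsl_thickness_um:.0f} um, "
      f"permeability {truth.permeability:.2f} of baseline")

swir_stack, rois = synth.render_swir_stack(truth, config)
thermal_stack, _ = synth.render_thermal_stack(truth, config)

res_i = analyze_stack(swir_stack, rois)
res_q = analyze_stack(thermal_stack, rois)
print(f"SWIR   dI_L={res_i.delta_lesion:8.1f}  dI_C={res_i.delta_control:8.1f}  "
      f"L-C={res_i.diff:8.1f}  L/C={res_i.ratio:5.2f}")
print(f"thermal dQ_L={res_q.delta_lesion:7.2f}  dQ_C={res_q.delta_control:7.2f}  "
      f"L-C={res_q.diff:7.2f} K*s  L/C={res_q.ratio:5.2f}")
print("the lesion ROI dries faster and cools more than sound control tissue,")
print("so both L-C contrasts are well above zero: the lesion is still permeable")
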