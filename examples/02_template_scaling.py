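"""Scale the compartment template to one knee's anatomy.

Shows the two thickness modes: keeping the template's femoral-to-tibial
thickness ratio versus using the subject's measured femoral fraction.
"""

import kneedeg as kd
from kneedeg.geometry import TEMPLATE_MEASUREMENTS

subject, meas = kd.generate_cohort(10, seed=4)[3]
template = kd.build_template("medial")

for mode in ("fixed_ratio", "scaled_ratio"):
    mesh = kd.scale_mesh(template, TEMPLATE_MEASUREMENTS, meas, mode)
    q = kd.mesh_quality(mesh)
    print(
        f"{mode:12s} femoral {mesh.thickness_femoral:.3f} mm, "
        f"tibial {mesh.thickness_tibial:.3f} mm, "
        f"volume {kd.element_volumes(mesh).sum():.0f} mm^3, "
        f"min Jacobian {q['min_jacobian']:.2f}"
    )
# Both modes match the subject's joint space; they differ only in how the
# joint space is split between the femoral and tibial cartilage.
print(f"subject joint space {meas.js_medial:.3f} mm, "
      f"femoral fraction {meas.femoral_fraction_medial:.2f}")
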