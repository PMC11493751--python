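"""Full-field homogenization of a fiber-reinforced RVE.

Builds a periodic hex host mesh, embeds the fiber axes as corrected-modulus
truss elements, pulls the cube to 20% strain along the axons under periodic
boundary conditions with free transverse average stress, and reports the
Hill-Mandel volume averages plus the stress-localization ratio.
"""

from axonrve import (
    MacroDeformation,
    build_host_mesh,
    embed_fibers,
    face_traction_asymmetry,
    fit_diameter_model,
    fit_orientation_model,
    generate_rve,
    hill_mandel_gap,
    homogenize_stress,
    localized_metrics,
    solve_quasistatic,
    study_constituents,
    uniaxial_nominal_stress,
)
from axonrve.rve import PlacementConfig
from axonrve.synthetic import group_summary

summary, truncation, theta_max, vf = group_summary("control")
geom = generate_rve(
    fit_diameter_model(summary, truncation), fit_orientation_model(theta_max),
    vf, edge=4.0, config=PlacementConfig(rng_seed=3),
)
cs = study_constituents("control")

mesh = build_host_mesh(geom.edge, n_per_side=4)
fibers = embed_fibers(mesh, geom)
print(f"{geom.n_fibers} fibers -> {fibers.n_trusses} embedded truss elements "
      f"tied to a {mesh.n}^3 hex grid ({mesh.n_nodes} nodes)")

sol = solve_quasistatic(mesh, fibers, cs, MacroDeformation(stretch=1.2, n_steps=5))
resp = homogenize_stress(sol)
for lam, P in zip(resp.stretch, resp.nominal_stress):
    print(f"  stretch {lam:.2f}: homogenized nominal stress {P:9.1f} Pa")
print(f"matrix alone would carry {uniaxial_nominal_stress(cs.ecm, 1.2):.1f} Pa at 20% strain;")
print("the aligned axon population stiffens the tissue several-fold.")

loc = localized_metrics(sol)
print(f"stress localization sigma_max/sigma_avg = {loc['sigma_max_over_avg']:.2f} "
      f"(1 means a homogeneous stress field)")
print(f"Hill-Mandel gap = {hill_mandel_gap(sol):.2e} (macro/micro work consistency)")
print(f"worst face-traction asymmetry = "
      f"{face_traction_asymmetry(sol)['worst_rel_asymmetry']:.2e} (t+ = -t- check)")
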