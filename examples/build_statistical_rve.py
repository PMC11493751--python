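"""Generate a periodic statistical RVE of the control-group white matter.

Packs non-overlapping cylindrical axons (GEV diameters, exponential
orientation dispersion, min gap 0.05 um) into an 8 um periodic cube until
the nominal volume fraction reaches the measured 32.106%, then validates
the geometry with the exhaustive pairwise oracle and a Monte-Carlo volume
cross-check.
"""

from axonrve import fit_diameter_model, fit_orientation_model, generate_rve, validate_geometry
from axonrve.rve import PlacementConfig
from axonrve.synthetic import group_summary
from axonrve.vtkio import write_fiber_polydata

summary, truncation, theta_max, vf_target = group_summary("control")
diam = fit_diameter_model(summary, truncation)
orient = fit_orientation_model(theta_max)

geom = generate_rve(diam, orient, vf_target, edge=8.0, config=PlacementConfig(rng_seed=0))
print(f"placed {geom.n_fibers} fibers in an {geom.edge} um cube")
print(f"nominal Vf (spanning-fiber accounting) = {geom.nominal_vf:.4f}")
print(f"effective Vf (clipped geometry)        = {geom.effective_vf:.4f}")
print("effective exceeds nominal slightly because tilted axons are longer than the edge")

report = validate_geometry(geom, n_mc=60_000)
print(f"min-gap violations: {len(report.violations)}; "
      f"Monte-Carlo Vf = {report.effective_vf_mc:.4f} "
      f"(|analytic - MC| = {report.vf_abs_error:.4f}, tolerance 0.005)")

write_fiber_polydata("control_rve.vtk", geom)
geom.to_json("control_rve.json")
print("wrote control_rve.json (full fiber records) and control_rve.vtk (axes for viewing)")
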