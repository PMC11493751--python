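# Methods

This note records the models, numerical choices and known limits of
`axonrve`, in the package's own words.

## Constituent model

Axons and extracellular matrix (ECM) are isotropic one-term Ogden solids in
principal stretches with a shared nonlinearity exponent `alpha` (the
exponent is insensitive to loading direction in soft neural tissue, so one
value serves both phases). Units: moduli in Pa, lengths in um, angles in
degrees, stresses in Pa. Calibrated defaults ship as a packaged JSON
fixture: control `mu_axon = 796.4 Pa`, `mu_ecm = 85.61 Pa`,
`alpha = 20.65`; preconditioned `598.4 / 98.97 / 21.55`, alongside
literature values for comparison.

Two incompressibility treatments coexist deliberately:

- **Closed-form paths** (uniaxial stress, the affine surrogate, the
  calibration forward model) use exact incompressibility `J = 1`; the
  volumetric term drops and the uniaxial nominal stress is
  `P(lam) = (2 mu/alpha)(lam^(alpha-1) - lam^(-alpha/2-1))`.
- **The FE path** enforces near-incompressibility by a volumetric penalty
  `(1/D)(J-1)^2` with bulk-to-shear ratio `K/mu = 1e4` by default
  (configurable; the study's hybrid elements publish no bulk value, so the
  ratio is this package's choice; it keeps `|J-1| < 1e-3` while staying
  well-conditioned). With the penalty active the shear term is evaluated at
  the deviatoric stretches `J^(-1/3) lam_i`. The plain-stretch shear energy
  carries a hydrostatic gradient `2 mu/alpha` at the identity, so combining
  it naively with a penalty would leave a spurious reference-state stress;
  the deviatoric form is exactly stress-free at `F = I` and coincides with
  the incompressible form on every `J = 1` path, so closed-form and
  calibrated quantities are unaffected.

The embedded-element stiffness correction subtracts the matrix energy
inside the fiber volume. With shared `alpha` the Ogden energy is linear in
`mu`, so the correction is exactly `mu* = mu_axon - mu_ecm`; matrix energy
over the whole cube plus corrected fiber energy reproduces the two-phase
energy identically.

## Histology distributions

Diameters: GEV(xi, nu, omega) truncated to the observed range (control
0.42–1.638 um, preconditioned 0.45–1.4 um). The study tissue's GEV
parameters are not published numerically, so they are recovered by matching
the truncated model's mean, variance and median to the measured summary
(control: 0.8646 um / 0.0634 um^2 / 0.8223 um) by damped least squares on
relative residuals; the fit must land within 1% of each statistic or it
raises. Truncated moments use 256-point Gauss–Legendre quadrature; the
median uses exact quantile inversion; sampling is inverse-CDF on the
truncated range. The measured summary is internally inconsistent (printed
sd 0.238 vs variance 0.0634); the variance column is used. scipy's
`genextreme` shape is the negative of `xi`; the wrapper hides this.

Orientations: deviation angle theta from the principal axonal axis follows
`H(y) = 1 - exp(-kappa y)`, hard-truncated at `theta_max`. An observed
range "0 to theta_max" is a sample range, not a distribution parameter, so
`theta_max` is interpreted as the 0.99 quantile:
`kappa = -ln(0.01)/theta_max`. Azimuth phi is uniform on [0, 360) deg. The
unit vector convention is `p = (cos th, sin th sin ph, sin th cos ph)` with
theta from +X (loading/axonal axis) and phi from +Z in the YZ plane. The
~2% of transversely running axons observed histologically are ignored.

## RVE generation

A periodic cube of edge `a` is packed with straight cylinders. Each fiber's
axis enters at the x = 0 face, traverses the cube once along x (axial
length `a / cos theta`) and wraps periodically through the y and z faces.
The diameter budget is drawn i.i.d. until the nominal (spanning-fiber)
fraction `pi sum d^2 / (4 a^2)` reaches the target, then fibers are placed
largest-first by rejection sampling over (orientation, anchor) — pure
sequential placement with per-attempt diameter redraw stalls near the
tissue's own 32% target because the joint probability of a small diameter
and a feasible anchor collapses; largest-first packs 20/20 seeds at edge
8 um in well under a second each. Overlap tests measure capped-segment
distances against all 26 periodic images plus the home copy and require
`(d1 + d2)/2 + 0.05 um`. A fiber's own wrap images are exempt (they are the
same axon continuing); for the near-aligned populations here self-images
are at least `a cos(theta_max)` away anyway.

Two volume fractions are reported: nominal (Eq.-26-style spanning
accounting, the stopping rule) and effective
`sum(A_i L_i)/a^3` from the clipped axes, which exceeds nominal by the mean
`1/cos theta` (~1–2% for the control dispersion). `validate_geometry`
re-derives the effective value by Monte-Carlo point sampling using
perpendicular-band (no end-cap) cylinder membership, which tiles the
periodic tube exactly and must agree with the analytic value within 0.005.
Published per-size fiber counts are not reproducible from the published
diameter statistics under any spanning-cylinder accounting; counts are
reported but not targeted.

## FE homogenization

Structured `n^3` trilinear hexahedra (2x2x2 Gauss) discretize the matrix
over the whole cube; fiber axes become finite-strain truss elements
(cross-section `pi d^2/4`, corrected modulus `mu*`, incompressible-rod
uniaxial response) whose nodes tie to the host by trilinear interpolation.
This replaces volumetric fiber meshes while preserving the embedded
kinematic coupling and the redundancy correction; it cannot represent
fiber bending or transverse fiber stiffness.

Periodic boundary conditions are built into the solution space: the total
displacement is `u = (F_bar - I) x + u*` and every set of periodically
identified nodes shares one fluctuation unknown; the fluctuation of the
grid-origin node is pinned to remove rigid translation (pinning any single
node is equivalent and does not affect stresses). An explicit
constraint-set view (`assemble_pbc`) exists for inspection and testing.

Loading modes: `uniaxial_stress` (default — prescribe the axial stretch,
secant-iterate the transverse stretch until the homogenized transverse
nominal stresses vanish, matching a tension test) and `prescribed`
(fully imposed diagonal or general `F_bar`); the published description is
ambiguous between the two, so both are exposed and none is asserted as
"the" protocol. Ten equal increments to 20% strain by default; Newton with
relative residual tolerance 1e-8 and step-halving on divergence (floor
1/64 of the increment). Hex element tangents are forward finite
differences of the analytic element internal-force vectors (symmetrized);
the truss tangent is analytic. Desk-scale defaults are edges 4–8 um with
2–8 elements per side (10^2–10^4 DOFs); tests run at <= 6 per side and the
sensitivity sweep declares its sizes in its output table.

Averaging: homogenized PK1 is the volume average of the matrix PK1 plus
`P_a (n x N)` rod terms; homogenized Cauchy uses deformed-volume weights
with `sigma_ax = lam_f P_a` for the (isochoric) rods. The localization
metric is max over quadrature points / fiber segments of the von Mises
equivalent Cauchy stress divided by its volume average (the norm is this
package's choice; none is published). The Hill–Mandel check perturbs the
converged state with a random macro increment plus a random periodic
fluctuation and verifies `<P : dF> = P_bar : dF_bar` to 1e-3 relative;
traction antisymmetry `t+ = -t-` is checked from boundary nodal forces.
At fixed geometry the homogenized stress is mesh-stable within a few
percent from 2 elements per side upward, while the localization ratio
*rises* toward a plateau with refinement (peaks resolve better); a
decreasing trend is not asserted.

## Affine surrogate

For the calibration loop (ms per evaluation): matrix closed-form uniaxial
response over the full volume plus corrected rods at the affine stretch
`lam_f = ||F_bar p||`, projected on the loading axis, with a frozen
direction population (default 200 draws, fixed seed) so the forward map is
deterministic. At `theta = 0` this is exactly the Voigt mixture
`(1-Vf) P_m(mu_ecm) + Vf P_f(mu_axon)` and coincides with the FE solution
for a single aligned spanning fiber; the FE response never exceeds it.
Tilting a fiber share softens the axial response monotonically up to
~60 deg; beyond that the (compressed) oblique rods give a shallow
stretch-dependent minimum before the contribution vanishes at 90 deg. The
surrogate makes no localized-stress claims.

## Calibration

The cost is the literal two-term composite above; the zero-strain point
(|stress| < 1e-12 Pa) is excluded from the relative-error term. ICA uses
the published settings (population 100, 10 imperialists, assimilation
gamma 0.3, stop when one empire remains with best cost <= 0.2) and
canonical choices where none are published: revolution rate 0.1,
empire cost = imperialist + 0.1 x mean colony cost, one weakest-colony
transfer per iteration, grid steps 0.1 Pa (moduli) and 0.01 (alpha) with
the excluded alpha values displaced to the nearest admissible grid point,
200 iterations maximum. The best-ever candidate is tracked, making the
reported trace monotone. A bound-sensitivity harness reruns with +/-20%
perturbed bounds.

Identifiability: with nearly aligned fibers the axial curve constrains
`alpha` and the combination `mu_ecm + Vf (mu_axon - mu_ecm)` tightly, but
the individual moduli trade off along a near-flat ridge (exactly flat at
`theta = 0`). Recovery experiments therefore score alpha, that
combination, fit cost and normalized RMSE — not the individual moduli.

## Synthetic data

Scenario specs freeze the study conditions (control: Vf 32.106%, 0–31 deg,
0.42–1.638 um; preconditioned: Vf 27.765%, 0–54.5 deg, 0.45–1.4 um) with
the calibrated constants as ground truth so synthetic curves live on the
tissue's 10^2–10^3 Pa scale. Synthetic tension curves carry 5%
multiplicative Gaussian noise by default (the published curves show error
bars but no numeric spread; 5% is this package's choice), preserve zero
stress at zero strain exactly, and run over 21 points to 20% strain.
Synthetic histology draws n axons per section from the fitted laws.

What the generator does not emulate: staining artifacts, axon damage and
loss (the measured 17% count reduction), curved or beaded axons, glial
cells/capillaries in the ECM, viscoelastic or poroelastic response, and
any coupling between preconditioning cycles and the distributions beyond
the printed endpoint statistics. Passing tests therefore demonstrate
internal consistency of the method chain on data with the assumed
statistical structure, not fidelity to raw micrographs or fresh-tissue
experiments.

## Known limitations

- Embedded trusses omit fiber bending/transverse stiffness and
  fiber–matrix interface mechanics (no slip, no damage).
- The penalty formulation caps the attainable incompressibility; mixed
  u-p elements are out of scope.
- Desk-scale meshes underresolve localization compared to the study's
  ~2e4-node models; localized metrics are qualitative at these sizes.
- Printed per-size fiber counts and the bracketed fit metrics of the
  original calibration depend on unpublished raw curves and are shipped as
  reference metadata only.
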