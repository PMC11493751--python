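# axonrve

Histology-informed micromechanics of brain white matter. `axonrve` builds
statistical representative volume elements (RVEs) of axon-reinforced white
matter from measured axon-diameter and orientation statistics, homogenizes
their finite-strain response with an embedded-element finite-element solver
under periodic boundary conditions, and inversely identifies the
constituent hyperelastic constants from uniaxial tension curves with an
imperialist competitive algorithm (ICA). It is aimed at tissue
biomechanicians studying how microstructure — axonal volume fraction,
diameter spread, orientation dispersion — shapes the macroscopic response
of white matter, for example before and after mechanical preconditioning.

## Model

Both constituents (axons and extracellular matrix, ECM) are isotropic
one-term Ogden solids,

```
psi = (2 mu / alpha^2) (lam1^alpha + lam2^alpha + lam3^alpha - 3) + (1/D)(J - 1)^2 ,
```

with a shared nonlinearity exponent `alpha`, so three constants
(`mu_axon`, `mu_ecm`, `alpha`) describe the composite. Fibers are embedded
in the host matrix mesh by kinematic tying (embedded element technique);
the double-counted matrix volume inside the fibers is removed by the
stiffness-redundancy correction `mu* = mu_axon - mu_ecm`. Axon diameters
follow a truncated generalized extreme value law GEV(xi, nu, omega), the
in-plane deviation angle theta an exponential law `H(y) = 1 - exp(-kappa y)`
truncated at the observed range. RVEs are periodic cubes packed by random
sequential placement (min surface gap 0.05 um) until the nominal volume
fraction `Vf = pi sum(d_i^2) / (4 a^2)` reaches the target. Macroscopic
stress follows Hill–Mandel volume averaging of the first Piola–Kirchhoff
stress; calibration minimizes the composite cost

```
Cost = (1/N) sum_i ((sM_i - sE_i)/sE_i)^2  +  sum_i (sM_i - sE_i)^2 / sum_i (sE_i - mean(sE))^2
```

(the second term equals `1 - R^2`) over `mu_axon in [100, 2000] Pa`,
`mu_ecm in [1, 500] Pa`, `alpha in [-30, 30] \ {-1, 0, 1}`.

## Worked example

```sh
python examples/build_statistical_rve.py
```

```
placed 30 fibers in an 8.0 um cube
nominal Vf (spanning-fiber accounting) = 0.3262
effective Vf (clipped geometry)        = 0.3283
effective exceeds nominal slightly because tilted axons are longer than the edge
min-gap violations: 0; Monte-Carlo Vf = 0.3304 (|analytic - MC| = 0.0022, tolerance 0.005)
```

Thirty axons drawn from the control-group diameter law (mean 0.86 um,
truncated to 0.42–1.638 um) and orientation law (0–31 deg) fill an 8 um
periodic cube to the measured 32.1% volume fraction; the exhaustive
pairwise oracle confirms no fiber pair violates the 0.05 um minimum gap,
and an independent Monte-Carlo estimate confirms the stored volume
fraction. `examples/homogenize_embedded_fe.py` then pulls such a cube to
20% strain:

```
  stretch 1.20: homogenized nominal stress     958.3 Pa
matrix alone would carry 297.2 Pa at 20% strain;
stress localization sigma_max/sigma_avg = 3.51
Hill-Mandel gap = 4.69e-14
```

— the aligned axon population stiffens the tissue roughly three-fold over
the bare matrix and concentrates stress around the fibers, while the
macro/micro work balance holds to machine precision. The other examples
cover the constituent closed forms, distribution fitting, ICA calibration
and the control-vs-preconditioned comparison; each prints a short
explanation with its numbers. A thin CLI mirrors the library
(`axonrve synth|fit-histology|generate-rve|homogenize|calibrate|sensitivity`).

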