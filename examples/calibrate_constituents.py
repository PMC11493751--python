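"""Inverse calibration by the imperialist competitive algorithm.

Generates a noiseless synthetic tension curve for the control scenario with
the affine backend, then recovers constituent constants with ICA using the
study's optimizer settings (population 100, 10 imperialists, gamma 0.3,
bounds mu_axon 100-2000 Pa, mu_ecm 1-500 Pa, alpha -30..30 \\ {-1,0,1}).
"""

import dataclasses

import numpy as np

from axonrve import IcaConfig, run_ica
from axonrve.calibration import normalized_rmse
from axonrve.synthetic import make_preconditioning_scenario, make_synthetic_curve, scenario_forward

control, _ = make_preconditioning_scenario()
control = dataclasses.replace(control, noise_sd=0.0)
truth = (control.mu_axon_Pa, control.mu_ecm_Pa, control.alpha)
curve = make_synthetic_curve(control)
forward = scenario_forward(control)
print(f"target curve: noiseless, ground truth mu_axon={truth[0]}, mu_ecm={truth[1]}, alpha={truth[2]}")

res = run_ica(forward, curve, config=IcaConfig(rng_seed=42))
b = res.best_params
print(f"ICA finished after {res.n_iterations} iterations, "
      f"{res.empire_counts[-1]} empire(s) remaining")
print(f"best candidate: mu_axon={b['mu_axon_Pa']} Pa, mu_ecm={b['mu_ecm_Pa']} Pa, alpha={b['alpha']}")
print(f"cost = {res.best_cost.total:.3g} (stop rule <= 0.2), R^2 = {res.best_cost.r_squared:.5f}")
print(f"normalized RMSE of the fitted curve = {normalized_rmse(forward(*res.best_array), curve):.3g}%")

vf = control.volume_fraction
comb_truth = truth[1] + vf * (truth[0] - truth[1])
comb_best = b["mu_ecm_Pa"] + vf * (b["mu_axon_Pa"] - b["mu_ecm_Pa"])
print(f"identifiable axial stiffness mu_ecm + Vf(mu_axon - mu_ecm): "
      f"truth {comb_truth:.1f} Pa, recovered {comb_best:.1f} Pa")
print("alpha and this combination are well identified; the individual moduli")
print("trade off along a near-flat ridge when the axons are nearly aligned.")
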