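{
  "description": "Calibrated one-term Ogden constants for bovine corona-radiata white matter constituents (control vs preconditioned), plus literature values for comparison. Shear moduli in Pa, alpha dimensionless.",
  "study": {
    "control": {
      "group": "control",
      "mu_axon_Pa": 796.4,
      "mu_ecm_Pa": 85.61,
      "alpha": 20.65,
      "d_penalty": 0.0,
      "min_cost": 0.1672,
      "r_squared": 0.975,
      "rmse": 0.121
    },
    "preconditioned": {
      "group": "preconditioned",
      "mu_axon_Pa": 598.4,
      "mu_ecm_Pa": 98.97,
      "alpha": 21.55,
      "d_penalty": 0.0,
      "min_cost": 0.1858,
      "r_squared": 0.961,
      "rmse": 0.197
    }
  },
  "literature": [
    {"source": "Chavoshnejad et al.", "mu_axon_Pa": 722.0, "alpha_axon": -23.0, "mu_ecm_Pa": 110.0, "alpha_ecm": -6.0},
    {"source": "Hoursan et al. (RVE)", "mu_axon_Pa": 1062.78, "alpha_axon": 4.89, "mu_ecm_Pa": 80.12, "alpha_ecm": 4.89},
    {"source": "Hoursan et al. (SVE)", "mu_axon_Pa": 738.3, "alpha_axon": 4.49, "mu_ecm_Pa": 99.36, "alpha_ecm": 4.49},
    {"source": "Yousefsani et al.", "mu_axon_Pa": 1130.3, "alpha_axon": 4.91, "mu_ecm_Pa": 87.4, "alpha_ecm": 4.91},
    {"source": "Pan et al.", "mu_axon_Pa": 33280.0, "alpha_axon": 8.22, "mu_ecm_Pa": 11093.0, "alpha_ecm": 8.22},
    {"source": "Meaney", "mu_axon_Pa": 290.82, "alpha_axon": 6.16, "mu_ecm_Pa": null, "alpha_ecm": null},
    {"source": "Saeidi et al.", "mu_axon_Pa": 80.8, "alpha_axon": 62.3, "mu_ecm_Pa": 353.5, "alpha_ecm": -21.5}
  ],
  "histology": {
    "control": {
      "n_axons": 115, "n_axons_sd": 3,
      "mean_um": 0.8646, "sd_um": 0.238, "range_um": 1.2095,
      "median_um": 0.8223, "variance_um2": 0.0634,
      "d_min_um": 0.42, "d_max_um": 1.638,
      "theta_max_deg": 31.0, "volume_fraction": 0.32106
    },
    "preconditioned": {
      "n_axons": 98, "n_axons_sd": 2,
      "mean_um": 0.8637, "sd_um": 0.251, "range_um": 0.9525,
      "median_um": 0.8615, "variance_um2": 0.0567,
      "d_min_um": 0.45, "d_max_um": 1.4,
      "theta_max_deg": 54.5, "volume_fraction": 0.27765
    }
  }
}
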