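"""Synthetic study data: scenario definitions, stress-strain curves and
histology tables with the statistical structure the analysis assumes.

Two scenarios mirror the study conditions.  Control: axonal volume fraction
32.106%, orientation range 0-31 deg, diameters truncated to [0.42, 1.638]
um.  Preconditioned: 27.765%, 0-54.5 deg, [0.45, 1.4] um.  Ground-truth
constituent constants default to the calibrated study values, so synthetic
outputs live on the tissue's stress scales (10^2-10^3 Pa).  Synthetic
tension curves run to 20% strain with 5% multiplicative Gaussian noise by
default (noiseless curves are exact forward-model output).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .calibration import ExperimentalCurve
from .errors import ParameterError
from .histology import (
    DiameterDistribution,
    HistologySummary,
    OrientationDistribution,
    fit_diameter_model,
    fit_orientation_model,
    sample_orientations,
)
from .materials import ConstituentSet, load_reference_constants
from .surrogate import make_affine_forward

__all__ = [
    "ScenarioSpec",
    "make_preconditioning_scenario",
    "make_synthetic_curve",
    "make_synthetic_histology",
    "group_summary",
]

_FIT_CACHE: dict[tuple, DiameterDistribution] = {}


def group_summary(group: str) -> tuple[HistologySummary, tuple[float, float], float, float]:
    """Measured diameter summary, truncation bounds, theta_max and Vf for a
    study group."""
    rec = load_reference_constants()["histology"]
    if group not in rec:
        raise ParameterError(f"unknown group {group!r}")
    h = rec[group]
    summary = HistologySummary(
        n_axons=h["n_axons"],
        mean=h["mean_um"],
        sd=h["sd_um"],
        median=h["median_um"],
        variance=h["variance_um2"],
        value_range=h["range_um"],
    )
    return summary, (h["d_min_um"], h["d_max_um"]), h["theta_max_deg"], h["volume_fraction"]


@dataclass
class ScenarioSpec:
    """All inputs one study arm needs, JSON-serializable."""

    group: str  # 'control' | 'preconditioned'
    volume_fraction: float
    theta_max_deg: float
    d_min_um: float
    d_max_um: float
    mu_axon_Pa: float
    mu_ecm_Pa: float
    alpha: float
    noise_sd: float = 0.05  # multiplicative, on stress
    strain_max: float = 0.20
    n_points: int = 21

    def __post_init__(self):
        if self.noise_sd < 0.0:
            raise ParameterError("noise sd must be >= 0")

    @property
    def constituents(self) -> ConstituentSet:
        return ConstituentSet.from_moduli(self.mu_axon_Pa, self.mu_ecm_Pa, self.alpha)

    @property
    def strain_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.strain_max, self.n_points)

    def orientation_model(self, cap_quantile: float = 0.99) -> OrientationDistribution:
        return fit_orientation_model(self.theta_max_deg, cap_quantile)

    def diameter_model(self) -> DiameterDistribution:
        key = (self.group, self.d_min_um, self.d_max_um)
        if key not in _FIT_CACHE:
            summary, trunc, _, _ = group_summary(self.group)
            _FIT_CACHE[key] = fit_diameter_model(summary, trunc)
        return _FIT_CACHE[key]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioSpec":
        return cls(**json.loads(text))


def make_preconditioning_scenario() -> tuple[ScenarioSpec, ScenarioSpec]:
    """The (control, preconditioned) scenario pair with study defaults."""
    ref = load_reference_constants()["study"]
    out = []
    for group in ("control", "preconditioned"):
        _, trunc, theta_max, vf = group_summary(group)
        row = ref[group]
        out.append(
            ScenarioSpec(
                group=group,
                volume_fraction=vf,
                theta_max_deg=theta_max,
                d_min_um=trunc[0],
                d_max_um=trunc[1],
                mu_axon_Pa=row["mu_axon_Pa"],
                mu_ecm_Pa=row["mu_ecm_Pa"],
                alpha=row["alpha"],
            )
        )
    return tuple(out)


def scenario_forward(spec: ScenarioSpec, n_dirs: int = 200, dir_seed: int = 12345):
    """Deterministic affine forward model for one scenario."""
    return make_affine_forward(
        spec.orientation_model(),
        spec.volume_fraction,
        1.0 + spec.strain_grid,
        n_dirs=n_dirs,
        rng_seed=dir_seed,
    )


def make_synthetic_curve(
    spec: ScenarioSpec, backend: str = "affine", rng_seed: int | None = None
) -> ExperimentalCurve:
    """Synthetic uniaxial tension curve for a scenario.

    backend 'affine' evaluates the reduced-order model; 'fe' runs the full
    embedded-fiber homogenization on a freshly generated RVE (slow).
    Multiplicative Gaussian noise of the scenario's sd is applied to the
    stresses; the zero-strain point stays exactly zero.
    """
    strain = spec.strain_grid
    if backend == "affine":
        stress = scenario_forward(spec)(spec.mu_axon_Pa, spec.mu_ecm_Pa, spec.alpha)
    elif backend == "fe":
        stress = _fe_curve(spec, rng_seed)
    else:
        raise ParameterError(f"unknown backend {backend!r}")
    stress = np.asarray(stress, dtype=float)
    if spec.noise_sd > 0.0:
        rng = np.random.default_rng(rng_seed)
        stress = stress * (1.0 + spec.noise_sd * rng.standard_normal(len(stress)))
        stress[strain == 0.0] = 0.0
    return ExperimentalCurve(strain=strain, stress=stress)


def _fe_curve(spec: ScenarioSpec, rng_seed, edge: float = 4.0, n_per_side: int = 4):
    from .fe import MacroDeformation, build_host_mesh, embed_fibers, homogenize_stress, solve_quasistatic
    from .rve import PlacementConfig, generate_rve

    geom = generate_rve(
        spec.diameter_model(),
        spec.orientation_model(),
        spec.volume_fraction,
        edge,
        PlacementConfig(rng_seed=rng_seed),
    )
    mesh = build_host_mesh(edge, n_per_side)
    fib = embed_fibers(mesh, geom)
    macro = MacroDeformation(stretch=1.0 + spec.strain_max, n_steps=spec.n_points - 1)
    sol = solve_quasistatic(mesh, fib, spec.constituents, macro)
    resp = homogenize_stress(sol)
    return np.interp(1.0 + spec.strain_grid, resp.stretch, resp.nominal_stress)


def make_synthetic_histology(
    spec: ScenarioSpec, n_axons: int, rng_seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic diameter and orientation tables in the histology CSV schema
    ((sample_id, group, diameter_um) and (sample_id, group, theta_deg))."""
    if n_axons <= 0:
        raise ParameterError("n_axons must be positive")
    rng = np.random.default_rng(rng_seed)
    d = spec.diameter_model().sample(n_axons, rng)
    theta, _, _ = sample_orientations(spec.orientation_model(), n_axons, rng)
    ids = np.arange(1, n_axons + 1)
    diam = pd.DataFrame({"sample_id": ids, "group": spec.group, "diameter_um": d})
    orient = pd.DataFrame({"sample_id": ids, "group": spec.group, "theta_deg": theta})
    return diam, orient
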