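"""Orchestration: run configuration and the mesh/edge sensitivity sweeps.

The sweeps mirror the study's protocol: mesh sweeps refine the host grid at
fixed geometry; edge sweeps regenerate statistical RVEs at fixed mesh
density for edge lengths 4-14 um (several seeds each) and report the
homogenized stress at 20% strain and the stress-localization ratio
sigma_max/sigma_avg.  A point is flagged converged when it changes by less
than 2% from the previous size; the recommended edge is the smallest whose
overall and localized responses both change by less than 5% versus the next
edge, averaged over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import AxonRveError, ParameterError
from .fe import (
    MacroDeformation,
    SolverConfig,
    build_host_mesh,
    embed_fibers,
    homogenize_stress,
    localized_metrics,
    solve_quasistatic,
)
from .rve import PlacementConfig, generate_rve
from .synthetic import ScenarioSpec, make_preconditioning_scenario

__all__ = ["RunConfig", "sensitivity_sweep", "select_edge"]

MESH_CONVERGENCE_RTOL = 0.02
EDGE_SELECTION_RTOL = 0.05


@dataclass
class RunConfig:
    """Desk-scale run settings; all randomized stages record their seeds."""

    group: str = "control"
    backend: str = "fe"
    edges_um: list = field(default_factory=lambda: list(range(4, 15)))
    mesh_densities: list = field(default_factory=lambda: [2, 4, 6])
    seeds: list = field(default_factory=lambda: [0, 1, 2])
    stretch: float = 1.2
    n_steps: int = 5
    n_per_side: int = 4
    fiber_resolution: float = 2.0
    solver: SolverConfig = field(default_factory=SolverConfig)
    output_dir: str = "runs"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            rec = yaml.safe_load(fh) or {}
        solver = SolverConfig(**rec.pop("solver", {}))
        return cls(solver=solver, **rec)

    def to_yaml(self, path) -> None:
        rec = {
            k: v for k, v in self.__dict__.items() if k != "solver"
        }
        rec["solver"] = dict(self.solver.__dict__)
        with open(path, "w") as fh:
            yaml.safe_dump(rec, fh)

    def scenario(self) -> ScenarioSpec:
        control, precond = make_preconditioning_scenario()
        return control if self.group == "control" else precond


def _solve_point(spec, geom, edge, n_per_side, config: RunConfig):
    mesh = build_host_mesh(edge, n_per_side)
    fib = embed_fibers(mesh, geom, config.fiber_resolution) if geom is not None else None
    macro = MacroDeformation(stretch=config.stretch, n_steps=config.n_steps)
    sol = solve_quasistatic(mesh, fib, spec.constituents, macro, config.solver)
    resp = homogenize_stress(sol)
    loc = localized_metrics(sol)
    return {
        "stress_Pa": float(resp.nominal_stress[-1]),
        "sigma_max_over_avg": loc["sigma_max_over_avg"],
        "n_nodes": mesh.n_nodes,
    }


def sensitivity_sweep(kind: str, config: RunConfig, homogeneous: bool = False) -> pd.DataFrame:
    """Mesh or edge sensitivity table.

    kind 'mesh': one fixed geometry (first seed), host densities from
    config.mesh_densities.  kind 'edge': regenerated RVEs for every
    (edge, seed) pair.  ``homogeneous`` drops the fibers (pure-matrix
    control case with an exact analytic limit).  Nonconverged points are
    recorded with NaN responses and the sweep continues.
    """
    if kind not in ("mesh", "edge"):
        raise ParameterError("kind must be 'mesh' or 'edge'")
    spec = config.scenario()
    rows = []
    if kind == "mesh":
        edge = float(config.edges_um[0])
        geom = None
        if not homogeneous:
            geom = generate_rve(
                spec.diameter_model(), spec.orientation_model(),
                spec.volume_fraction, edge, PlacementConfig(rng_seed=config.seeds[0]),
            )
        for n in config.mesh_densities:
            row = {"kind": "mesh", "size": n, "edge_um": edge, "seed": config.seeds[0]}
            try:
                row.update(_solve_point(spec, geom, edge, int(n), config))
            except AxonRveError:
                row.update({"stress_Pa": np.nan, "sigma_max_over_avg": np.nan, "n_nodes": np.nan})
            rows.append(row)
    else:
        for edge in config.edges_um:
            for seed in config.seeds:
                row = {"kind": "edge", "size": float(edge), "edge_um": float(edge), "seed": seed}
                try:
                    geom = None
                    if not homogeneous:
                        geom = generate_rve(
                            spec.diameter_model(), spec.orientation_model(),
                            spec.volume_fraction, float(edge), PlacementConfig(rng_seed=seed),
                        )
                    row.update(_solve_point(spec, geom, float(edge), config.n_per_side, config))
                except AxonRveError:
                    row.update({"stress_Pa": np.nan, "sigma_max_over_avg": np.nan, "n_nodes": np.nan})
                rows.append(row)
    df = pd.DataFrame(rows)
    # convergence flag: successive mean responses change < 2%
    means = df.groupby("size")["stress_Pa"].mean()
    flags = {}
    prev = None
    for size, val in means.items():
        flags[size] = (
            prev is not None
            and np.isfinite(val)
            and np.isfinite(prev)
            and abs(val - prev) <= MESH_CONVERGENCE_RTOL * abs(prev)
        )
        prev = val
    df["converged_vs_previous"] = df["size"].map(flags)
    return df


def select_edge(edge_sweep: pd.DataFrame, rtol: float = EDGE_SELECTION_RTOL) -> float:
    """Smallest edge whose seed-averaged stress and localization ratio both
    change by less than rtol versus the next edge."""
    g = edge_sweep.groupby("size")[["stress_Pa", "sigma_max_over_avg"]].mean()
    sizes = list(g.index)
    for a, b in zip(sizes[:-1], sizes[1:]):
        ds = abs(g.loc[b, "stress_Pa"] - g.loc[a, "stress_Pa"]) / abs(g.loc[a, "stress_Pa"])
        dr = abs(g.loc[b, "sigma_max_over_avg"] - g.loc[a, "sigma_max_over_avg"]) / abs(
            g.loc[a, "sigma_max_over_avg"]
        )
        if ds < rtol and dr < rtol:
            return float(a)
    return float(sizes[-1])
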