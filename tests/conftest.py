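"""Shared fixtures: study constants, fitted distributions, small solved RVEs.

Expensive objects (distribution fits, FE solves) are session-scoped; every
randomized fixture carries an explicit seed.
"""

import numpy as np
import pytest

from axonrve.fe import (
    MacroDeformation,
    build_host_mesh,
    embed_fibers,
    solve_quasistatic,
)
from axonrve.histology import (
    HistologySummary,
    fit_diameter_model,
    fit_orientation_model,
)
from axonrve.materials import ConstituentSet, study_constituents
from axonrve.rve import PlacementConfig, generate_rve

CONTROL_SUMMARY = HistologySummary(
    n_axons=115, mean=0.8646, sd=0.238, median=0.8223, variance=0.0634, value_range=1.2095
)
CONTROL_TRUNCATION = (0.42, 1.638)
CONTROL_THETA_MAX = 31.0
CONTROL_VF = 0.32106


@pytest.fixture(scope="session")
def control_constituents() -> ConstituentSet:
    return study_constituents("control")


@pytest.fixture(scope="session")
def preconditioned_constituents() -> ConstituentSet:
    return study_constituents("preconditioned")


@pytest.fixture(scope="session")
def control_summary() -> HistologySummary:
    return CONTROL_SUMMARY


@pytest.fixture(scope="session")
def control_diameters():
    return fit_diameter_model(CONTROL_SUMMARY, CONTROL_TRUNCATION)


@pytest.fixture(scope="session")
def control_orientations():
    return fit_orientation_model(CONTROL_THETA_MAX)


@pytest.fixture(scope="session")
def small_rve(control_diameters, control_orientations):
    """A small (edge 4 um) control-scenario RVE, fixed seed."""
    return generate_rve(
        control_diameters,
        control_orientations,
        CONTROL_VF,
        4.0,
        PlacementConfig(rng_seed=3),
    )


@pytest.fixture(scope="session")
def solved_fiber_rve(small_rve, control_constituents):
    """Converged embedded-fiber homogenization of the small control RVE."""
    mesh = build_host_mesh(small_rve.edge, 4)
    fibers = embed_fibers(mesh, small_rve)
    return solve_quasistatic(
        mesh,
        fibers,
        control_constituents,
        MacroDeformation(stretch=1.2, n_steps=5, mode="uniaxial_stress"),
    )


@pytest.fixture(scope="session")
def solved_homogeneous(control_constituents):
    """Pure-matrix solve (equal constituent moduli => corrected mu* = 0)."""
    ecm = control_constituents.ecm
    homog = ConstituentSet.from_moduli(ecm.mu, ecm.mu, ecm.alpha)
    mesh = build_host_mesh(4.0, 2)
    return solve_quasistatic(
        mesh, None, homog, MacroDeformation(stretch=1.2, n_steps=5, mode="uniaxial_stress")
    )
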