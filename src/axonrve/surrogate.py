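"""Affine reduced-order homogenization (fiber-as-rod).

A fast forward model for the calibration loop: the macroscopic kinematics
are the incompressible uniaxial-stress solution of the matrix,
F = diag(lam, lam^-1/2, lam^-1/2).  Following the embedded-element energy
split psi_total = psi_m + sum psi_c, the matrix contributes its closed-form
isotropic Ogden nominal stress over the full volume; each fiber direction p
adds a corrected Ogden rod (mu_f* = mu_f - mu_m) at the affine axial
stretch lam_f = ||F p||, its nominal-stress tensor P_a (n x p) projected
onto the loading axis and weighted by the fiber's volume-fraction share.
For aligned fibers this reduces to the Voigt rule of mixtures
(1 - Vf) P_m(mu_ecm) + Vf P_f(mu_axon), which the full-field FE response
cannot exceed.  The reduction is affine (no periodic fluctuation) and is
never used for localized (sigma_max) quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .histology import OrientationDistribution, sample_orientations
from .materials import ConstituentSet, corrected_fiber_params, uniaxial_nominal_stress

__all__ = [
    "SurrogateInput",
    "affine_stress_curve",
    "affine_axial_stress",
    "fixed_direction_set",
    "make_affine_forward",
]


@dataclass
class SurrogateInput:
    """Constituents + fiber population for the affine model.

    directions: (K, 3) unit vectors; shares: (K,) volume-fraction shares
    summing to the total fiber volume fraction (< 1).
    """

    constituents: ConstituentSet
    directions: np.ndarray
    shares: np.ndarray
    stretches: np.ndarray

    def __post_init__(self):
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.shares = np.atleast_1d(np.asarray(self.shares, dtype=float))
        self.stretches = np.atleast_1d(np.asarray(self.stretches, dtype=float))
        if len(self.directions) != len(self.shares):
            raise ParameterError("directions and shares must have equal length")
        if self.total_vf >= 1.0:
            raise ParameterError("total fiber volume fraction must be < 1")

    @property
    def total_vf(self) -> float:
        return float(self.shares.sum())


def affine_axial_stress(
    constituents: ConstituentSet,
    directions: np.ndarray,
    shares: np.ndarray,
    stretches: np.ndarray,
) -> np.ndarray:
    """Axial nominal stress P11(lam) of the affine composite model."""
    lam = np.atleast_1d(np.asarray(stretches, dtype=float))
    p = np.atleast_2d(np.asarray(directions, dtype=float))
    w = np.atleast_1d(np.asarray(shares, dtype=float))
    vf = float(w.sum())
    if vf >= 1.0:
        raise ParameterError("total fiber volume fraction must be < 1")
    # matrix at full weight: the embedded split counts it over the whole
    # volume, the fiber rods carry the corrected modulus mu* = mu_f - mu_m
    P_m = np.asarray(uniaxial_nominal_stress(constituents.ecm, lam))
    if len(p) == 0 or vf == 0.0:
        return P_m
    fiber = corrected_fiber_params(constituents.axon, constituents.ecm)
    # affine fiber stretch under F = diag(lam, lam^-1/2, lam^-1/2)
    px2 = p[:, 0] ** 2
    pt2 = 1.0 - px2
    lam_f = np.sqrt(np.outer(lam**2, px2) + np.outer(1.0 / lam, pt2))  # (M, K)
    P_a = uniaxial_nominal_stress(fiber, lam_f)
    # current direction x-component: n_x = lam * p_x / lam_f
    n_x = lam[:, None] * p[None, :, 0] / lam_f
    contrib = P_a * n_x * p[None, :, 0]  # project P_a (n x p) onto e1 x e1
    return P_m + contrib @ w


def affine_stress_curve(inp: SurrogateInput) -> "HomogenizedResponse":
    """Full stretch-vs-nominal-stress curve of the affine model."""
    from .fe import HomogenizedResponse

    P11 = affine_axial_stress(inp.constituents, inp.directions, inp.shares, inp.stretches)
    # Cauchy axial stress on the incompressible path: sigma = lam * P
    return HomogenizedResponse(
        stretch=inp.stretches,
        nominal_stress=np.asarray(P11),
        cauchy_stress=np.asarray(P11) * inp.stretches,
    )


def fixed_direction_set(
    orient_dist: OrientationDistribution, total_vf: float, n_dirs: int = 200, rng_seed: int = 12345
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic equal-share fiber population drawn once from the
    orientation law; reused across calibration evaluations."""
    _, _, p = sample_orientations(orient_dist, n_dirs, rng_seed)
    shares = np.full(n_dirs, total_vf / n_dirs)
    return p, shares


def make_affine_forward(
    orient_dist: OrientationDistribution,
    total_vf: float,
    stretches: np.ndarray,
    n_dirs: int = 200,
    rng_seed: int = 12345,
):
    """Forward model (mu_axon, mu_ecm, alpha) -> nominal stresses on the grid.

    The fiber direction population is frozen at construction, so the forward
    map is deterministic — required both for inverse calibration and for
    noiseless synthetic curves.
    """
    p, shares = fixed_direction_set(orient_dist, total_vf, n_dirs, rng_seed)
    lam = np.asarray(stretches, dtype=float)

    def forward(mu_axon: float, mu_ecm: float, alpha: float) -> np.ndarray:
        cs = ConstituentSet.from_moduli(mu_axon, mu_ecm, alpha)
        return affine_axial_stress(cs, p, shares, lam)

    forward.directions = p
    forward.shares = shares
    forward.stretches = lam
    return forward
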