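"""One-term Ogden hyperelasticity for white-matter constituents.

Both axons and extracellular matrix (ECM) are modelled as isotropic one-term
Ogden solids with strain-energy density (per unit reference volume)

    psi(F) = (2 mu / alpha^2) (lam1^alpha + lam2^alpha + lam3^alpha - 3)
             + (1/D) (J - 1)^2,

where lam_i are principal stretches, J = det F, mu is the shear-like modulus,
alpha the strain-sensitive nonlinearity exponent, and D a volumetric
compliance.  D = 0 encodes exact incompressibility (J = 1): closed-form paths
drop the volumetric term; the finite-element path enforces near-
incompressibility by a penalty with a configurable bulk-to-shear ratio.
When the penalty is active the shear term is evaluated at the deviatoric
stretches lam_bar_i = J^(-1/3) lam_i (the hybrid-element convention), so the
reference state is exactly stress-free; on J = 1 paths the two forms
coincide.

When fibers are embedded into a host matrix mesh, the fiber volume is counted
twice (host elements fill the whole cube).  The stiffness-redundancy
correction subtracts the matrix energy inside the fiber region,
psi_c = psi_f - psi_m, which for a shared alpha reduces to the corrected
modulus mu_f* = mu_f - mu_m.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .errors import DomainError, ParameterError

__all__ = [
    "OgdenParams",
    "ConstituentSet",
    "ogden_energy",
    "uniaxial_nominal_stress",
    "pk1_stress",
    "cauchy_from_pk1",
    "corrected_fiber_params",
    "principal_stretches",
    "load_reference_constants",
    "study_constituents",
]

#: default bulk-to-shear ratio used when a near-incompressible penalty
#: parameter is derived from mu (FE path); keeps |J - 1| < 1e-3 in practice.
DEFAULT_BULK_RATIO = 1.0e4


@dataclass(frozen=True)
class OgdenParams:
    """Hyperelastic constants of one constituent.

    Parameters
    ----------
    mu : float
        Shear modulus, Pa.  Positive for physical constituents; corrected
        fiber parameters (mu_f* = mu_f - mu_m) may carry any real value.
    alpha : float
        Dimensionless nonlinearity exponent.  alpha = 0 makes the energy
        singular and is rejected.
    d_penalty : float
        Volumetric compliance D, 1/Pa.  0 encodes exact incompressibility
        (the volumetric term is dropped).
    """

    mu: float
    alpha: float
    d_penalty: float = 0.0

    def __post_init__(self):
        if self.alpha == 0.0:
            raise ParameterError("alpha = 0 makes the Ogden energy singular")
        if self.d_penalty < 0.0:
            raise ParameterError("volumetric compliance d_penalty must be >= 0")

    def with_bulk_ratio(self, ratio: float = DEFAULT_BULK_RATIO) -> "OgdenParams":
        """Return a copy with the penalty set so that K = ratio * |mu|.

        The volumetric energy (1/D)(J-1)^2 has initial bulk modulus K = 2/D,
        hence D = 2 / (ratio * |mu|).
        """
        if ratio <= 0:
            raise ParameterError("bulk-to-shear ratio must be positive")
        if self.mu == 0.0:
            return replace(self, d_penalty=0.0)
        return replace(self, d_penalty=2.0 / (ratio * abs(self.mu)))


@dataclass(frozen=True)
class ConstituentSet:
    """Axon + ECM parameter pair sharing a single alpha.

    The nonlinearity exponent is insensitive to loading direction, so one
    alpha describes both constituents and three independent constants
    (mu_axon, mu_ecm, alpha) fully characterise the white-matter composite.
    """

    axon: OgdenParams
    ecm: OgdenParams

    def __post_init__(self):
        if self.axon.alpha != self.ecm.alpha:
            raise ParameterError(
                "axon and ECM must share alpha "
                f"(got {self.axon.alpha} vs {self.ecm.alpha})"
            )

    @property
    def alpha(self) -> float:
        return self.axon.alpha

    @property
    def corrected_fiber(self) -> OgdenParams:
        return corrected_fiber_params(self.axon, self.ecm)

    @classmethod
    def from_moduli(cls, mu_axon: float, mu_ecm: float, alpha: float) -> "ConstituentSet":
        return cls(OgdenParams(mu_axon, alpha), OgdenParams(mu_ecm, alpha))


def principal_stretches(F: np.ndarray) -> tuple[np.ndarray, float]:
    """Principal stretches and J of a deformation gradient.

    Raises
    ------
    DomainError
        If det F <= 0.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise DomainError(f"det F = {J:g} must be positive")
    C = F.T @ F
    lam = np.sqrt(np.clip(np.linalg.eigvalsh(C), 0.0, None))
    return lam, J


def ogden_energy(params: OgdenParams, stretches) -> float:
    """Strain-energy density (Pa) at the given principal stretches.

    With d_penalty = 0 this is the exactly incompressible shear energy at
    the given stretches.  With d_penalty > 0 the shear term uses deviatoric
    stretches J^(-1/3) lam_i and the volumetric term (1/D)(J-1)^2 is added,
    so the undeformed state carries zero stress.
    """
    lam = np.asarray(stretches, dtype=float)
    if lam.shape != (3,):
        raise ParameterError("stretches must be three values")
    if np.any(lam <= 0.0):
        raise DomainError("principal stretches must be positive")
    mu, a = params.mu, params.alpha
    if params.d_penalty > 0.0:
        J = float(np.prod(lam))
        lam_bar = lam * J ** (-1.0 / 3.0)
        psi = (2.0 * mu / a**2) * (np.sum(lam_bar**a) - 3.0)
        psi += (J - 1.0) ** 2 / params.d_penalty
    else:
        psi = (2.0 * mu / a**2) * (np.sum(lam**a) - 3.0)
    return float(psi)


def uniaxial_nominal_stress(params: OgdenParams, stretch) -> float | np.ndarray:
    """Nominal (first Piola-Kirchhoff) axial stress on the incompressible
    uniaxial path lam = (lam, lam^-1/2, lam^-1/2):

        P(lam) = (2 mu / alpha) (lam^(alpha-1) - lam^(-alpha/2-1)).

    Accepts a scalar or an array of stretches.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0):
        raise DomainError("stretch must be positive")
    mu, a = params.mu, params.alpha
    P = (2.0 * mu / a) * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
    return float(P) if np.isscalar(stretch) else P


def pk1_stress(params: OgdenParams, F: np.ndarray) -> np.ndarray:
    """First Piola-Kirchhoff stress P = d psi / d F, Pa.

    Computed spectrally: with C = F^T F = sum lam_i^2 N_i (x) N_i,
    S = sum (1/lam_i)(d psi/d lam_i) N_i (x) N_i and P = F S.
    """
    F = np.asarray(F, dtype=float)
    _ = principal_stretches(F)  # validates det F > 0
    return _pk1_batch(params, F[None, :, :])[0]


def _pk1_batch(params: OgdenParams, F: np.ndarray) -> np.ndarray:
    """Batched PK1 for an (..., 3, 3) stack of deformation gradients."""
    mu, a, d = params.mu, params.alpha, params.d_penalty
    C = np.einsum("...ji,...jk->...ik", F, F)
    w, V = np.linalg.eigh(C)
    lam = np.sqrt(np.clip(w, 1e-30, None))
    if d > 0.0:
        # deviatoric form: d psi / d lam_i = (2mu/a)(lam_bar_i^a - s/3)/lam_i
        # with s = sum lam_bar^a, plus the volumetric penalty
        J = np.prod(lam, axis=-1, keepdims=True)
        lam_bar = lam * J ** (-1.0 / 3.0)
        pow_a = lam_bar**a
        s = np.sum(pow_a, axis=-1, keepdims=True)
        dpsi = (2.0 * mu / a) * (pow_a - s / 3.0) / lam
        dpsi = dpsi + (2.0 / d) * (J - 1.0) * J / lam
    else:
        dpsi = (2.0 * mu / a) * lam ** (a - 1.0)
    coef = dpsi / lam  # S eigenvalues
    S = np.einsum("...ik,...k,...jk->...ij", V, coef, V)
    return np.einsum("...ij,...jk->...ik", F, S)


def _energy_batch(params: OgdenParams, F: np.ndarray) -> np.ndarray:
    mu, a, d = params.mu, params.alpha, params.d_penalty
    C = np.einsum("...ji,...jk->...ik", F, F)
    lam = np.sqrt(np.clip(np.linalg.eigvalsh(C), 1e-30, None))
    if d > 0.0:
        J = np.prod(lam, axis=-1)
        lam_bar = lam * J[..., None] ** (-1.0 / 3.0)
        psi = (2.0 * mu / a**2) * (np.sum(lam_bar**a, axis=-1) - 3.0)
        psi = psi + (J - 1.0) ** 2 / d
    else:
        psi = (2.0 * mu / a**2) * (np.sum(lam**a, axis=-1) - 3.0)
    return psi


def cauchy_from_pk1(P: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Cauchy stress sigma = J^-1 P F^T (batched)."""
    J = np.linalg.det(F)
    return np.einsum("...ij,...kj->...ik", P, F) / J[..., None, None]


def corrected_fiber_params(axon: OgdenParams, ecm: OgdenParams) -> OgdenParams:
    """Stiffness-redundancy corrected fiber parameters mu_f* = mu_f - mu_m.

    Adding the corrected fiber energy (inside the fiber volume) to the host
    matrix energy reproduces the true fiber energy exactly, because for a
    shared alpha the Ogden energy is linear in mu.
    """
    if axon.alpha != ecm.alpha:
        raise ParameterError(
            f"corrected fiber needs a shared alpha (got {axon.alpha} vs {ecm.alpha})"
        )
    return OgdenParams(mu=axon.mu - ecm.mu, alpha=axon.alpha, d_penalty=0.0)


# ---------------------------------------------------------------------------
# packaged reference constants


def load_reference_constants() -> dict:
    """Packaged calibrated and literature constituent constants.

    Returns the raw JSON record: keys ``study`` (control / preconditioned
    rows with mu_axon_Pa, mu_ecm_Pa, alpha and fit metadata), ``literature``
    and ``histology`` (per-group diameter summary statistics, orientation
    range and axonal volume fraction).
    """
    path = resources.files("axonrve.data").joinpath("reference_constants.json")
    with path.open("r") as fh:
        return json.load(fh)


def study_constituents(group: str = "control") -> ConstituentSet:
    """ConstituentSet for one study group ('control' or 'preconditioned')."""
    rec = load_reference_constants()["study"]
    if group not in rec:
        raise ParameterError(f"unknown group {group!r}; expected one of {sorted(rec)}")
    row = rec[group]
    return ConstituentSet.from_moduli(row["mu_axon_Pa"], row["mu_ecm_Pa"], row["alpha"])
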