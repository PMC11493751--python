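"""Ogden constitutive model: closed forms, stress-energy consistency,
objectivity and the embedded-element stiffness correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axonrve.errors import DomainError, ParameterError
from axonrve.materials import (
    ConstituentSet,
    OgdenParams,
    corrected_fiber_params,
    load_reference_constants,
    ogden_energy,
    pk1_stress,
    principal_stretches,
    uniaxial_nominal_stress,
)

CONTROL_ECM = OgdenParams(mu=85.61, alpha=20.65)
CONTROL_AXON = OgdenParams(mu=796.4, alpha=20.65)


def uniaxial_F(lam: float) -> np.ndarray:
    return np.diag([lam, lam**-0.5, lam**-0.5])


def random_admissible_F(rng, scale=0.15) -> np.ndarray:
    """Random deformation gradient near identity with det F > 0."""
    while True:
        F = np.eye(3) + rng.uniform(-scale, scale, size=(3, 3))
        if np.linalg.det(F) > 0.3:
            return F


class TestEnergy:
    def test_undeformed_energy_is_zero(self):
        assert ogden_energy(CONTROL_ECM, (1.0, 1.0, 1.0)) == 0.0

    def test_energy_linear_in_mu(self):
        lam = (1.3, 0.9, 1.3**-1 / 0.9)
        e1 = ogden_energy(OgdenParams(50.0, 8.0), lam)
        e2 = ogden_energy(OgdenParams(100.0, 8.0), lam)
        assert e2 == pytest.approx(2.0 * e1, rel=1e-14)

    def test_energy_matches_arbitrary_precision_evaluation(self):
        """Term-by-term evaluation of the energy at 50 digits (sympy)."""
        sympy = pytest.importorskip("sympy")
        lam1 = sympy.Rational(12, 10)
        mu = sympy.Rational(8561, 100)
        alpha = sympy.Rational(2065, 100)
        lam_t = 1 / sympy.sqrt(lam1)
        psi = 2 * mu / alpha**2 * (lam1**alpha + 2 * lam_t**alpha - 3)
        expected = float(psi.evalf(50))
        got = ogden_energy(CONTROL_ECM, (1.2, 1.2**-0.5, 1.2**-0.5))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(DomainError):
            ogden_energy(CONTROL_ECM, (1.0, -0.2, 1.0))

    def test_alpha_zero_rejected_at_type_level(self):
        with pytest.raises(ParameterError):
            OgdenParams(mu=100.0, alpha=0.0)

    def test_volumetric_penalty_enters_energy(self):
        p = OgdenParams(mu=100.0, alpha=5.0, d_penalty=1e-3)
        # pure dilatation: deviatoric part vanishes, only the penalty remains
        J = 1.1**3
        assert ogden_energy(p, (1.1, 1.1, 1.1)) == pytest.approx((J - 1) ** 2 / 1e-3, rel=1e-12)
        # on an isochoric path the penalized and incompressible forms agree
        lam = (1.3, 0.9, 1.0 / (1.3 * 0.9))
        assert ogden_energy(p, lam) == pytest.approx(
            ogden_energy(OgdenParams(100.0, 5.0), lam), rel=1e-12
        )


class TestUniaxialStress:
    def test_reference_state_stress_free(self):
        assert uniaxial_nominal_stress(CONTROL_AXON, 1.0) == 0.0

    def test_sign_follows_loading_direction(self):
        assert uniaxial_nominal_stress(CONTROL_ECM, 1.1) > 0
        assert uniaxial_nominal_stress(CONTROL_ECM, 0.9) < 0

    def test_small_strain_modulus_is_three_mu(self):
        """dP/dlam at lam -> 1 equals 3 mu for incompressible uniaxial."""
        h = 1e-6
        slope = (
            uniaxial_nominal_stress(CONTROL_ECM, 1 + h)
            - uniaxial_nominal_stress(CONTROL_ECM, 1 - h)
        ) / (2 * h)
        assert slope == pytest.approx(3 * CONTROL_ECM.mu, rel=1e-5)

    def test_matches_energy_derivative_along_incompressible_path(self):
        """Closed form == central finite difference of the energy along
        lam = (lam, lam^-1/2, lam^-1/2)."""
        lam, h = 1.2, 1e-6

        def path_energy(x):
            return ogden_energy(CONTROL_AXON, (x, x**-0.5, x**-0.5))

        fd = (path_energy(lam + h) - path_energy(lam - h)) / (2 * h)
        assert uniaxial_nominal_stress(CONTROL_AXON, lam) == pytest.approx(fd, rel=1e-7)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(DomainError):
            uniaxial_nominal_stress(CONTROL_ECM, 0.0)


class TestPk1:
    def test_identity_gives_zero_stress(self):
        P = pk1_stress(OgdenParams(100.0, 6.0, d_penalty=1e-4), np.eye(3))
        assert np.allclose(P, 0.0, atol=1e-8)

    def test_negative_jacobian_rejected(self):
        with pytest.raises(DomainError):
            pk1_stress(CONTROL_ECM, -np.eye(3))

    @given(seed=st.integers(0, 50))
    @settings(max_examples=15, deadline=None)
    def test_gradient_of_energy(self, seed):
        """Every PK1 component matches the central finite difference of the
        energy with respect to that component of F (1e-6 relative)."""
        rng = np.random.default_rng(seed)
        params = OgdenParams(
            mu=float(rng.uniform(20, 900)),
            alpha=float(rng.uniform(2, 22)),
            d_penalty=2.0 / (1e3 * 500.0),
        )
        F = random_admissible_F(rng)
        P = pk1_stress(params, F)
        h = 1e-6
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                lam_p, _ = principal_stretches(Fp)
                lam_m, _ = principal_stretches(Fm)
                fd = (ogden_energy(params, lam_p) - ogden_energy(params, lam_m)) / (2 * h)
                assert P[i, j] == pytest.approx(fd, rel=1e-6, abs=1e-6 * params.mu)

    def test_objectivity_under_rotation(self):
        rng = np.random.default_rng(4)
        F = random_admissible_F(rng)
        A = rng.normal(size=(3, 3))
        R, _ = np.linalg.qr(A)
        if np.linalg.det(R) < 0:
            R[:, 0] *= -1
        params = OgdenParams(200.0, 9.0, d_penalty=1e-5)
        assert np.allclose(pk1_stress(params, R @ F), R @ pk1_stress(params, F), rtol=1e-9, atol=1e-9)

    def test_cauchy_stress_symmetric(self):
        rng = np.random.default_rng(7)
        F = random_admissible_F(rng)
        params = OgdenParams(150.0, 12.0, d_penalty=1e-5)
        P = pk1_stress(params, F)
        sig = P @ F.T / np.linalg.det(F)
        assert np.allclose(sig, sig.T, rtol=1e-9, atol=1e-9)

    def test_uniaxial_closed_form_agrees_with_pk1_on_path(self):
        """Incompressible uniaxial P11 minus the pressure term reproduces the
        closed form: P11 - lam_t/lam * P22 with P from the D=0 energy."""
        lam = 1.17
        F = uniaxial_F(lam)
        P = pk1_stress(CONTROL_ECM, F)
        # pressure from the lateral traction-free condition of the
        # incompressible problem: P_uni = P11 - p/lam with p = lam_t * P22
        p = P[1, 1] * lam**-0.5
        closed = uniaxial_nominal_stress(CONTROL_ECM, lam)
        assert (P[0, 0] - p / lam) == pytest.approx(closed, rel=1e-8)


class TestCorrection:
    def test_equal_moduli_make_fiber_invisible(self):
        p = OgdenParams(85.61, 20.65)
        assert corrected_fiber_params(p, p).mu == 0.0

    @pytest.mark.parametrize(
        "group, expected",
        [("control", 710.79), ("preconditioned", 499.43)],
    )
    def test_corrected_moduli_from_study_constants(self, group, expected):
        rec = load_reference_constants()["study"][group]
        axon = OgdenParams(rec["mu_axon_Pa"], rec["alpha"])
        ecm = OgdenParams(rec["mu_ecm_Pa"], rec["alpha"])
        assert corrected_fiber_params(axon, ecm).mu == pytest.approx(expected, abs=1e-9)

    def test_mismatched_alpha_rejected(self):
        with pytest.raises(ParameterError):
            corrected_fiber_params(OgdenParams(700, 20.0), OgdenParams(80, 21.0))
        with pytest.raises(ParameterError):
            ConstituentSet(OgdenParams(700, 20.0), OgdenParams(80, 21.0))

    @given(seed=st.integers(0, 30))
    @settings(max_examples=10, deadline=None)
    def test_volume_redundancy_identity(self, seed):
        """psi_m(F) + psi_c(F) == psi_f(F) exactly for shared alpha."""
        rng = np.random.default_rng(seed)
        axon = OgdenParams(float(rng.uniform(200, 1500)), 15.0)
        ecm = OgdenParams(float(rng.uniform(10, 199)), 15.0)
        corr = corrected_fiber_params(axon, ecm)
        lam, _ = principal_stretches(random_admissible_F(rng))
        psi_m = ogden_energy(ecm, lam)
        psi_c = ogden_energy(corr, lam)
        psi_f = ogden_energy(axon, lam)
        assert psi_m + psi_c == pytest.approx(psi_f, rel=1e-12)
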