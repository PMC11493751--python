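"""Axon diameter and orientation statistics.

Diameters follow a generalized extreme value (GEV) law with shape xi,
location nu (um) and scale omega (um), truncated to the observed range
[d_min, d_max].  In-plane deviation angles theta from the principal axonal
axis follow an exponential law H(y; kappa) = 1 - exp(-kappa y) hard-truncated
at theta_max; the azimuth phi is uniform on [0, 360) degrees.

The GEV parameters are not tabulated for this tissue, so they are recovered
by matching the truncated model's mean, variance and median to the measured
summary statistics via numerical least squares.  kappa is likewise recovered
from the reported angular range interpreted as a high quantile (default
0.99) of the exponential law.

Angle convention: theta is measured from +X (the primary axonal direction),
phi from +Z within the YZ plane, so the unit orientation vector is
p = (cos theta, sin theta sin phi, sin theta cos phi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DomainError, FitError, InputError, ParameterError

__all__ = [
    "DiameterDistribution",
    "OrientationDistribution",
    "HistologySummary",
    "OrientationVector",
    "fit_diameter_model",
    "fit_orientation_model",
    "sample_diameters",
    "sample_orientation",
    "sample_orientations",
    "summarize_measurements",
    "angles_to_unit_vectors",
]


@dataclass(frozen=True)
class HistologySummary:
    """Per-group summary of axon diameter measurements (um)."""

    n_axons: float
    mean: float
    sd: float
    median: float
    variance: float
    value_range: float  # max - min

    def as_row(self) -> dict:
        return {
            "N": self.n_axons,
            "mean_um": self.mean,
            "sd_um": self.sd,
            "max_min_um": self.value_range,
            "median_um": self.median,
            "variance_um2": self.variance,
        }


def summarize_measurements(values) -> HistologySummary:
    """Arithmetic summary of a diameter sample (sample sd/variance, ddof=1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("cannot summarize an empty measurement list")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return HistologySummary(
        n_axons=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        median=float(np.median(arr)),
        variance=sd**2,
        value_range=float(arr.max() - arr.min()),
    )


# ---------------------------------------------------------------------------
# diameters: truncated GEV


@dataclass(frozen=True)
class DiameterDistribution:
    """GEV(xi, nu, omega) truncated to [d_min, d_max] um.

    scipy's ``genextreme`` uses the opposite sign convention for the shape
    (c = -xi); the wrapper keeps the xi convention in which xi > 0 gives a
    heavy right tail with support y > nu - omega/xi.
    """

    xi: float
    nu: float
    omega: float
    d_min: float
    d_max: float

    def __post_init__(self):
        if self.omega <= 0.0:
            raise ParameterError("GEV scale omega must be positive")
        if not self.d_min < self.d_max:
            raise ParameterError("need d_min < d_max")

    @cached_property
    def _frozen(self):
        return stats.genextreme(c=-self.xi, loc=self.nu, scale=self.omega)

    def support(self) -> tuple[float, float]:
        """Untruncated GEV support."""
        if self.xi > 0.0:
            return (self.nu - self.omega / self.xi, math.inf)
        if self.xi < 0.0:
            return (-math.inf, self.nu - self.omega / self.xi)
        return (-math.inf, math.inf)

    def pdf(self, y) -> float | np.ndarray:
        """Untruncated GEV density, 1/um.  Raises outside the support."""
        arr = np.asarray(y, dtype=float)
        lo, hi = self.support()
        if np.any(arr < lo) or np.any(arr > hi):
            raise DomainError("y outside the GEV support")
        out = self._frozen.pdf(arr)
        return float(out) if np.isscalar(y) else out

    def cdf(self, y) -> float | np.ndarray:
        """Untruncated GEV cumulative probability (saturates at 0/1)."""
        out = self._frozen.cdf(np.asarray(y, dtype=float))
        return float(out) if np.isscalar(y) else out

    # -- truncated model ---------------------------------------------------

    @cached_property
    def _trunc_cdf_bounds(self) -> tuple[float, float]:
        return float(self.cdf(self.d_min)), float(self.cdf(self.d_max))

    def truncated_pdf(self, y) -> np.ndarray:
        c0, c1 = self._trunc_cdf_bounds
        arr = np.asarray(y, dtype=float)
        out = np.where(
            (arr >= self.d_min) & (arr <= self.d_max),
            self._frozen.pdf(arr) / (c1 - c0),
            0.0,
        )
        return out

    def truncated_cdf(self, y) -> np.ndarray:
        c0, c1 = self._trunc_cdf_bounds
        arr = np.clip(np.asarray(y, dtype=float), self.d_min, self.d_max)
        return (self._frozen.cdf(arr) - c0) / (c1 - c0)

    def truncated_ppf(self, q) -> np.ndarray:
        c0, c1 = self._trunc_cdf_bounds
        return self._frozen.ppf(c0 + np.asarray(q, dtype=float) * (c1 - c0))

    def truncated_moments(self, n_quad: int = 256) -> tuple[float, float, float]:
        """(mean, variance, median) of the truncated law by Gauss-Legendre
        quadrature on [d_min, d_max] and exact quantile inversion."""
        x, w = np.polynomial.legendre.leggauss(n_quad)
        y = 0.5 * (self.d_max - self.d_min) * x + 0.5 * (self.d_max + self.d_min)
        wy = 0.5 * (self.d_max - self.d_min) * w
        g = self.truncated_pdf(y)
        mean = float(np.sum(wy * y * g))
        var = float(np.sum(wy * (y - mean) ** 2 * g))
        median = float(self.truncated_ppf(0.5))
        return mean, var, median

    def sample(self, n: int, rng) -> np.ndarray:
        """Inverse-CDF sampling restricted to [d_min, d_max]."""
        rng = np.random.default_rng(rng)
        if n == 0:
            return np.empty(0)
        u = rng.uniform(size=int(n))
        return np.asarray(self.truncated_ppf(u), dtype=float)


def sample_diameters(dist: DiameterDistribution, n: int, rng_seed) -> np.ndarray:
    return dist.sample(n, rng_seed)


def fit_diameter_model(
    summary: HistologySummary,
    truncation: tuple[float, float],
    tol: float = 0.01,
) -> DiameterDistribution:
    """Fit (xi, nu, omega) so the truncated model reproduces the summary.

    Matches the truncated mean, variance and median within ``tol`` relative
    (default 1%) by damped least squares on the relative residuals.

    Raises
    ------
    FitError
        For degenerate input (zero variance, median outside the truncation
        range) or when the residual tolerance cannot be met.
    """
    d_min, d_max = truncation
    if summary.variance <= 0.0:
        raise FitError("summary variance must be positive to fit a model")
    if not (d_min < summary.median < d_max):
        raise FitError("summary median lies outside the truncation range")

    target = np.array([summary.mean, summary.variance, summary.median])

    def residuals(x):
        xi, nu, log_omega = x
        try:
            dist = DiameterDistribution(xi, nu, math.exp(log_omega), d_min, d_max)
            m, v, md = dist.truncated_moments()
        except (ParameterError, FloatingPointError):
            return np.full(3, 1e3)
        got = np.array([m, v, md])
        if not np.all(np.isfinite(got)):
            return np.full(3, 1e3)
        return (got - target) / target

    best = None
    for xi0 in (0.05, -0.2, 0.3, -0.5):
        x0 = np.array([xi0, summary.median, math.log(max(summary.sd, 1e-3))])
        sol = optimize.least_squares(
            residuals,
            x0,
            bounds=([-2.0, d_min - 5.0, -10.0], [2.0, d_max + 5.0, 3.0]),
            xtol=1e-12,
            ftol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if np.max(np.abs(sol.fun)) < tol:
            best = sol
            break
    res = np.max(np.abs(best.fun))
    if res >= tol:
        raise FitError(
            f"truncated GEV cannot match the summary within {tol:.0%} "
            f"(worst relative residual {res:.3g})"
        )
    xi, nu, log_omega = best.x
    return DiameterDistribution(float(xi), float(nu), math.exp(log_omega), d_min, d_max)


# ---------------------------------------------------------------------------
# orientations: truncated exponential on theta, uniform phi


@dataclass(frozen=True)
class OrientationDistribution:
    """Exponential deviation-angle law, hard-truncated at theta_max degrees."""

    kappa: float
    theta_max: float

    def __post_init__(self):
        if self.kappa <= 0.0:
            raise ParameterError("exponential rate kappa must be positive")
        if not 0.0 < self.theta_max <= 90.0:
            raise ParameterError("theta_max must lie in (0, 90] degrees")

    def cdf(self, y) -> float | np.ndarray:
        """Untruncated exponential CDF H(y) = 1 - exp(-kappa y)."""
        out = 1.0 - np.exp(-self.kappa * np.asarray(y, dtype=float))
        return float(out) if np.isscalar(y) else out

    def sample_theta(self, n: int, rng) -> np.ndarray:
        """Inverse-CDF draws from the exponential truncated to [0, theta_max]."""
        rng = np.random.default_rng(rng)
        cap = float(self.cdf(self.theta_max))
        u = rng.uniform(0.0, cap, size=int(n))
        return -np.log1p(-u) / self.kappa


def fit_orientation_model(theta_max: float, cap_quantile: float = 0.99) -> OrientationDistribution:
    """Interpret an observed angular range [0, theta_max] as the cap_quantile
    of an exponential law: kappa = -ln(1 - cap_quantile) / theta_max."""
    if theta_max <= 0.0:
        raise ParameterError("theta_max must be positive")
    if not 0.0 < cap_quantile < 1.0:
        raise ParameterError("cap_quantile must lie in (0, 1)")
    kappa = -math.log1p(-cap_quantile) / theta_max
    return OrientationDistribution(kappa=kappa, theta_max=theta_max)


@dataclass(frozen=True)
class OrientationVector:
    """One sampled fiber orientation (degrees) and its unit vector."""

    theta: float
    phi: float
    p: tuple[float, float, float]


def angles_to_unit_vectors(theta_deg, phi_deg) -> np.ndarray:
    """p = (cos th, sin th sin ph, sin th cos ph), theta from +X, phi from +Z."""
    th = np.radians(np.asarray(theta_deg, dtype=float))
    ph = np.radians(np.asarray(phi_deg, dtype=float))
    return np.stack(
        [np.cos(th), np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph)], axis=-1
    )


def sample_orientations(dist: OrientationDistribution, n: int, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw n orientations; returns (theta_deg, phi_deg, unit vectors (n,3))."""
    rng = np.random.default_rng(rng)
    theta = dist.sample_theta(n, rng)
    phi = rng.uniform(0.0, 360.0, size=int(n))
    return theta, phi, angles_to_unit_vectors(theta, phi)


def sample_orientation(dist: OrientationDistribution, rng_seed) -> OrientationVector:
    theta, phi, p = sample_orientations(dist, 1, rng_seed)
    return OrientationVector(float(theta[0]), float(phi[0]), tuple(p[0]))


# ---------------------------------------------------------------------------
# CSV schemas


def summaries_to_frame(rows: dict[str, HistologySummary]) -> pd.DataFrame:
    """Summary table mirroring the printed diameter-statistics layout."""
    return pd.DataFrame(
        [{"group": g, **s.as_row()} for g, s in rows.items()]
    ).set_index("group")


def read_diameter_table(path) -> pd.DataFrame:
    """Read a (sample_id, group, diameter_um) CSV."""
    df = pd.read_csv(path)
    missing = {"sample_id", "group", "diameter_um"} - set(df.columns)
    if missing:
        raise InputError(f"diameter table missing columns {sorted(missing)}")
    return df


def read_orientation_table(path) -> pd.DataFrame:
    """Read a (sample_id, group, theta_deg) CSV."""
    df = pd.read_csv(path)
    missing = {"sample_id", "group", "theta_deg"} - set(df.columns)
    if missing:
        raise InputError(f"orientation table missing columns {sorted(missing)}")
    return df
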