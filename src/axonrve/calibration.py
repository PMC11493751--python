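"""Inverse identification of (mu_axon, mu_ECM, alpha) by the imperialist
competitive algorithm (ICA).

The composite cost compares a model stress curve sigma_M against the
experimental curve sigma_E on a shared strain grid:

    Cost = (1/N) sum_i ((sigma_M_i - sigma_E_i) / sigma_E_i)^2
         + sum_i (sigma_M_i - sigma_E_i)^2 / sum_i (sigma_E_i - mean)^2

The second term equals 1 - R^2 by construction; points with |sigma_E| below
1e-12 Pa (the zero-strain point) are excluded from the relative-error term.

The optimizer is the canonical ICA: an initial population on a discretized
box, the best candidates become imperialists, colonies assimilate toward
their imperialist (coefficient gamma), a fraction revolts to random
positions, a colony that beats its imperialist swaps roles, and the weakest
empire loses its weakest colony to a roulette-selected winner until one
empire remains.  Search bounds: mu_axon in [100, 2000] Pa, mu_ECM in
[1, 500] Pa, alpha in [-30, 30] excluding {-1, 0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, OptimizationError, ParameterError

__all__ = [
    "ExperimentalCurve",
    "SearchSpace",
    "IcaConfig",
    "CostBreakdown",
    "IcaResult",
    "cost",
    "run_ica",
]

_ZERO_STRESS = 1e-12


@dataclass
class ExperimentalCurve:
    """Uniaxial nominal stress-strain data (strain grid strictly increasing,
    zero stress at zero strain)."""

    strain: np.ndarray
    stress: np.ndarray  # nominal stress, Pa

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise InputError("strain and stress must be matching 1-D arrays")
        if np.any(np.diff(self.strain) <= 0.0):
            raise InputError("strain grid must be strictly increasing")
        if self.strain[0] == 0.0 and abs(self.stress[0]) > _ZERO_STRESS:
            raise InputError("stress at zero strain must vanish")

    @property
    def stretch(self) -> np.ndarray:
        return 1.0 + self.strain

    @property
    def n_points(self) -> int:
        return len(self.strain)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"strain": self.strain, "nominal_stress_Pa": self.stress}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExperimentalCurve":
        df = pd.read_csv(path)
        if "strain" in df.columns:
            strain = df["strain"].to_numpy()
        elif "stretch" in df.columns:
            strain = df["stretch"].to_numpy() - 1.0
        else:
            raise InputError("curve CSV needs a 'strain' or 'stretch' column")
        if "nominal_stress_Pa" not in df.columns:
            raise InputError("curve CSV needs a 'nominal_stress_Pa' column")
        return cls(strain=strain, stress=df["nominal_stress_Pa"].to_numpy())


@dataclass
class CostBreakdown:
    total: float
    relative_error_term: float
    residual_ratio_term: float  # = 1 - R^2

    @property
    def r_squared(self) -> float:
        return 1.0 - self.residual_ratio_term

    @property
    def rmse(self) -> float:
        return self._rmse

    _rmse: float = 0.0


def cost(model_stress, exp_curve: ExperimentalCurve) -> CostBreakdown:
    """Composite calibration cost of a model curve on the experimental grid."""
    sM = np.asarray(model_stress, dtype=float)
    sE = exp_curve.stress
    if sM.shape != sE.shape:
        raise InputError("model curve must share the experimental grid")
    nz = np.abs(sE) > _ZERO_STRESS
    n = len(sE)
    term1 = float(np.sum(((sM[nz] - sE[nz]) / sE[nz]) ** 2) / n)
    ss_res = float(np.sum((sM - sE) ** 2))
    ss_tot = float(np.sum((sE - sE.mean()) ** 2))
    term2 = ss_res / ss_tot if ss_tot > 0 else np.inf
    out = CostBreakdown(
        total=term1 + term2,
        relative_error_term=term1,
        residual_ratio_term=term2,
    )
    out._rmse = float(np.sqrt(ss_res / n))
    return out


@dataclass
class SearchSpace:
    """Discretized calibration box with the printed bounds and exclusions."""

    mu_axon_bounds: tuple[float, float] = (100.0, 2000.0)
    mu_ecm_bounds: tuple[float, float] = (1.0, 500.0)
    alpha_bounds: tuple[float, float] = (-30.0, 30.0)
    alpha_excluded: tuple[float, ...] = (-1.0, 0.0, 1.0)
    mu_step: float = 0.1
    alpha_step: float = 0.01

    @property
    def lows(self) -> np.ndarray:
        return np.array([self.mu_axon_bounds[0], self.mu_ecm_bounds[0], self.alpha_bounds[0]])

    @property
    def highs(self) -> np.ndarray:
        return np.array([self.mu_axon_bounds[1], self.mu_ecm_bounds[1], self.alpha_bounds[1]])

    @property
    def steps(self) -> np.ndarray:
        return np.array([self.mu_step, self.mu_step, self.alpha_step])

    def snap(self, x: np.ndarray) -> np.ndarray:
        """Project candidates onto the discretized grid, enforce bounds and
        push alpha off the excluded values."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        lo, hi, st = self.lows, self.highs, self.steps
        y = lo + np.round((x - lo) / st) * st
        y = np.clip(y, lo, hi)
        for ex in self.alpha_excluded:
            bad = np.abs(y[:, 2] - ex) < 0.5 * self.alpha_step
            y[bad, 2] = ex + self.alpha_step * np.where(y[bad, 2] >= ex, 1.0, -1.0)
        return y

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        ok = np.all((x >= self.lows - 1e-9) & (x <= self.highs + 1e-9), axis=1)
        for ex in self.alpha_excluded:
            ok &= np.abs(x[:, 2] - ex) > 1e-9
        return ok

    def sample(self, n: int, rng) -> np.ndarray:
        u = rng.uniform(size=(n, 3))
        return self.snap(self.lows + u * (self.highs - self.lows))


@dataclass
class IcaConfig:
    n_population: int = 100
    n_imperialists: int = 10
    assimilation: float = 0.3  # gamma
    revolution_rate: float = 0.1
    colony_cost_weight: float = 0.1
    max_iterations: int = 200
    stop_cost: float = 0.2
    rng_seed: int | None = None

    def __post_init__(self):
        if self.n_imperialists >= self.n_population:
            raise ParameterError("need fewer imperialists than the population")
        if self.stop_cost < 0.0:
            raise ParameterError("stop cost must be >= 0")


@dataclass
class IcaResult:
    best_params: dict  # mu_axon_Pa, mu_ecm_Pa, alpha
    best_cost: CostBreakdown
    history: np.ndarray  # best-ever total cost per iteration
    empire_counts: np.ndarray  # number of empires per iteration
    visited: np.ndarray  # (n_visited, 3) every evaluated candidate
    n_iterations: int
    converged: bool

    @property
    def best_array(self) -> np.ndarray:
        return np.array(
            [self.best_params["mu_axon_Pa"], self.best_params["mu_ecm_Pa"], self.best_params["alpha"]]
        )

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.history)),
                "best_cost": self.history,
                "n_empires": self.empire_counts,
            }
        )


class _Empire:
    __slots__ = ("imp", "imp_cost", "colonies", "colony_costs")

    def __init__(self, imp, imp_cost):
        self.imp = imp
        self.imp_cost = imp_cost
        self.colonies = []
        self.colony_costs = []

    def total_cost(self, w):
        mean_col = np.mean(self.colony_costs) if self.colony_costs else 0.0
        return self.imp_cost + w * mean_col


def run_ica(
    forward,
    exp_curve: ExperimentalCurve,
    space: SearchSpace | None = None,
    config: IcaConfig | None = None,
) -> IcaResult:
    """Imperialist-competitive search for (mu_axon, mu_ECM, alpha).

    ``forward`` maps (mu_axon, mu_ecm, alpha) to model stresses on the
    experimental grid.  Terminates when a single empire remains AND the best
    cost is at or below the stop threshold, or at max_iterations.
    """
    space = space or SearchSpace()
    config = config or IcaConfig()
    rng = np.random.default_rng(config.rng_seed)
    visited = []

    def evaluate(x) -> float:
        visited.append(np.array(x))
        try:
            c = cost(forward(*x), exp_curve).total
        except Exception:
            return np.inf
        return c if np.isfinite(c) else np.inf

    pop = space.sample(config.n_population, rng)
    costs = np.array([evaluate(x) for x in pop])
    if not np.any(np.isfinite(costs)):
        raise OptimizationError("no feasible candidate in the initial population")

    order = np.argsort(costs)
    n_imp = config.n_imperialists
    imp_idx = order[:n_imp]
    col_idx = order[n_imp:]
    # colonies distributed by normalized imperialist power
    power = costs[imp_idx].max() - costs[imp_idx] + 1e-12
    power = power / power.sum()
    counts = np.floor(power * len(col_idx)).astype(int)
    while counts.sum() < len(col_idx):
        counts[np.argmax(power)] += 1
    empires = []
    k = 0
    for e in range(n_imp):
        emp = _Empire(pop[imp_idx[e]].copy(), costs[imp_idx[e]])
        for _ in range(counts[e]):
            emp.colonies.append(pop[col_idx[k]].copy())
            emp.colony_costs.append(costs[col_idx[k]])
            k += 1
        empires.append(emp)

    best_i = int(order[0])
    best_x, best_c = pop[best_i].copy(), float(costs[best_i])
    history, empire_counts = [], []
    it = 0
    converged = False
    for it in range(1, config.max_iterations + 1):
        for emp in empires:
            for ci in range(len(emp.colonies)):
                colx = emp.colonies[ci]
                if rng.uniform() < config.revolution_rate:
                    newx = space.sample(1, rng)[0]
                else:
                    step = config.assimilation * rng.uniform(0.0, 2.0, size=3)
                    newx = space.snap(colx + step * (emp.imp - colx))[0]
                newc = evaluate(newx)
                emp.colonies[ci] = newx
                emp.colony_costs[ci] = newc
                if newc < emp.imp_cost:  # colony overthrows its imperialist
                    emp.colonies[ci], emp.imp = emp.imp.copy(), newx.copy()
                    emp.colony_costs[ci], emp.imp_cost = emp.imp_cost, newc
                if newc < best_c:
                    best_x, best_c = newx.copy(), float(newc)

        if len(empires) > 1:
            totals = np.array([e.total_cost(config.colony_cost_weight) for e in empires])
            weakest = int(np.argmax(totals))
            pw = totals.max() - totals + 1e-12
            pw[weakest] = 0.0
            pw = pw / pw.sum()
            winner = int(rng.choice(len(empires), p=pw))
            wk = empires[weakest]
            if wk.colonies:
                worst_col = int(np.argmax(wk.colony_costs))
                empires[winner].colonies.append(wk.colonies.pop(worst_col))
                empires[winner].colony_costs.append(wk.colony_costs.pop(worst_col))
                if not wk.colonies:  # empire collapses: imperialist captured
                    empires[winner].colonies.append(wk.imp)
                    empires[winner].colony_costs.append(wk.imp_cost)
                    empires.pop(weakest)
            else:
                empires[winner].colonies.append(wk.imp)
                empires[winner].colony_costs.append(wk.imp_cost)
                empires.pop(weakest)

        history.append(best_c)
        empire_counts.append(len(empires))
        if len(empires) == 1 and best_c <= config.stop_cost:
            converged = True
            break

    bd = cost(forward(*best_x), exp_curve)
    return IcaResult(
        best_params={
            "mu_axon_Pa": float(best_x[0]),
            "mu_ecm_Pa": float(best_x[1]),
            "alpha": float(best_x[2]),
        },
        best_cost=bd,
        history=np.array(history),
        empire_counts=np.array(empire_counts),
        visited=np.array(visited),
        n_iterations=it,
        converged=converged,
    )


def normalized_rmse(model_stress, exp_curve: ExperimentalCurve) -> float:
    """RMSE between curves normalized by the experimental stress range (%)"""
    sM = np.asarray(model_stress, dtype=float)
    sE = exp_curve.stress
    rng_ = sE.max() - sE.min()
    return float(np.sqrt(np.mean((sM - sE) ** 2)) / rng_ * 100.0)


def bound_sensitivity(
    forward,
    exp_curve: ExperimentalCurve,
    space: SearchSpace | None = None,
    config: IcaConfig | None = None,
    perturbation: float = 0.2,
) -> pd.DataFrame:
    """Rerun the calibration with the box bounds widened and narrowed by
    +/- perturbation to confirm the optimum is interior, per the study's
    bound-sensitivity protocol."""
    space = space or SearchSpace()
    config = config or IcaConfig()
    rows = []
    for label, f in (("nominal", 0.0), ("narrow", -perturbation), ("wide", perturbation)):
        s = SearchSpace(
            mu_axon_bounds=(space.mu_axon_bounds[0], space.mu_axon_bounds[1] * (1 + f)),
            mu_ecm_bounds=(space.mu_ecm_bounds[0], space.mu_ecm_bounds[1] * (1 + f)),
            alpha_bounds=(space.alpha_bounds[0] * (1 + f), space.alpha_bounds[1] * (1 + f)),
            mu_step=space.mu_step,
            alpha_step=space.alpha_step,
        )
        res = run_ica(forward, exp_curve, s, config)
        rows.append({"bounds": label, **res.best_params, "cost": res.best_cost.total})
    return pd.DataFrame(rows)
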