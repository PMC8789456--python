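"""Seagull optimization (SOA) and deer hunting optimization (DHO).

Both are population metaheuristics over a box-bounded continuous search
space, exposed through a common :class:`ObjectiveSpec` so that the same
machinery drives multilevel-Otsu threshold search (SOA) and classifier
hyperparameter tuning (DHO).

SOA alternates a migration phase — collision avoidance via a control
scalar A that decays linearly from f_c to 0, plus attraction toward the
best agent — with an attack phase that spirals logarithmically around the
best agent:

    A    = f_c - x * (f_c / max_iterations)
    C_s  = A * P_s
    B    = 2 * A^2 * r_d,              r_d ~ U[0, 1]
    M_s  = B * (P_bs - P_s)
    D_s  = |C_s + M_s|
    P_s' = D_s * x' * y' * z' + P_bs,  (x', y', z') a log-spiral draw
           with r = u * e^{k v}, k ~ U[0, 2*pi]

DHO guides a hunter population with the best (leader) and second-best
(successor) positions, a wind angle theta = 2*pi*a, and coefficients
Z = (1/4) * log(j + 1/j_max) * b (b ~ U[-1, 1]) and K = 2c (c ~ U[0, 1]):

    |K| < 1 : X' = X_s - Z * p * |K * X_s - X|      (explore via successor)
    p   < 1 : X' = X_l - Z * p * |K * X_l - X|      (encircle the leader)
    else    : X' = X_l - p * cos(theta) * |X_l - X| (angle update)

with p ~ U[0, 2] drawn per hunter.  Both optimizers clip to bounds, keep
an elitist best-so-far, and are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ObjectiveSpec",
    "SOAParams",
    "DHOParams",
    "OptimizeResult",
    "soa_optimize",
    "dho_optimize",
    "random_search",
]


@dataclass
class ObjectiveSpec:
    """A scalar objective over a box: callable, bounds and sense."""

    fun: Callable[[np.ndarray], float]
    bounds: Sequence[tuple[float, float]]
    sense: str = "minimize"

    def __post_init__(self) -> None:
        if self.sense not in ("minimize", "maximize"):
            raise ValueError(f"sense must be minimize|maximize, got {self.sense!r}")
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 2 or b.shape[0] == 0 or b.shape[1] != 2:
            raise ValueError("bounds must be a non-empty sequence of (low, high)")
        if np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("every dimension needs low < high")
        self._lo = b[:, 0]
        self._hi = b[:, 1]

    @property
    def dim(self) -> int:
        return self._lo.size

    def clip(self, positions: np.ndarray) -> np.ndarray:
        return np.clip(positions, self._lo, self._hi)

    def initial_population(self, m: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self._lo, self._hi, size=(m, self.dim))

    def evaluate(self, positions: np.ndarray) -> np.ndarray:
        """Internal fitness: lower is better; non-finite mapped to +inf."""
        sign = 1.0 if self.sense == "minimize" else -1.0
        vals = np.array([sign * float(self.fun(p)) for p in positions])
        vals[~np.isfinite(vals)] = np.inf
        return vals

    def external(self, internal_fitness: float) -> float:
        return internal_fitness if self.sense == "minimize" else -internal_fitness


@dataclass(frozen=True)
class SOAParams:
    population: int = 30
    max_iterations: int = 100
    f_c: float = 2.0
    spiral_u: float = 1.0
    spiral_v: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.f_c <= 0:
            raise ValueError("f_c must be > 0")


@dataclass(frozen=True)
class DHOParams:
    population: int = 30
    max_iterations: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class OptimizeResult:
    """Best position/fitness (in the caller's sense) and per-iteration history."""

    position: np.ndarray
    fitness: float
    history: list[float] = field(default_factory=list)

    def history_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "best_fitness"])
            for i, v in enumerate(self.history):
                w.writerow([i, v])


def _check_some_finite(best_fit: float) -> None:
    # non-finite agents are tolerated (worst fitness); error only when the
    # whole run never saw a finite value
    if not np.isfinite(best_fit):
        raise RuntimeError("objective returned non-finite values for every agent")


def soa_optimize(objective: ObjectiveSpec, params: SOAParams) -> OptimizeResult:
    """Run the seagull optimizer; best-so-far history is monotone."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    m, n_iter = params.population, params.max_iterations

    pos = objective.initial_population(m, rng)
    fit = objective.evaluate(pos)
    i_best = int(np.argmin(fit))
    best_pos, best_fit = pos[i_best].copy(), float(fit[i_best])
    history = []

    for x in range(1, n_iter + 1):  # A = f_c at x=0 (init), exactly 0 at x=n_iter
        a_ctrl = params.f_c - x * (params.f_c / n_iter)
        r_d = rng.random((m, 1))
        c_s = a_ctrl * pos
        b_ctrl = 2.0 * a_ctrl**2 * r_d
        m_s = b_ctrl * (best_pos[None, :] - pos)
        d_s = np.abs(c_s + m_s)
        k = rng.uniform(0.0, 2.0 * np.pi, (m, 1))
        r = params.spiral_u * np.exp(k * params.spiral_v)
        spiral = (r * np.cos(k)) * (r * np.sin(k)) * (r * k)
        pos = objective.clip(d_s * spiral + best_pos[None, :])
        fit = objective.evaluate(pos)
        i = int(np.argmin(fit))
        if fit[i] < best_fit:  # elitist, synchronous update
            best_fit = float(fit[i])
            best_pos = pos[i].copy()
        history.append(objective.external(best_fit))

    _check_some_finite(best_fit)
    return OptimizeResult(best_pos, objective.external(best_fit), history)


def dho_optimize(objective: ObjectiveSpec, params: DHOParams) -> OptimizeResult:
    """Run the deer hunting optimizer; best-so-far history is monotone."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    m, j_max = params.population, params.max_iterations

    pos = objective.initial_population(m, rng)
    fit = objective.evaluate(pos)
    order = np.argsort(fit, kind="stable")
    leader, leader_fit = pos[order[0]].copy(), float(fit[order[0]])
    successor = pos[order[1]].copy()
    history = []

    for j in range(1, j_max + 1):
        a = rng.random()
        theta = 2.0 * np.pi * a
        b = rng.uniform(-1.0, 1.0)
        c = rng.random()
        z = 0.25 * np.log(j + 1.0 / j_max) * b
        k_coef = 2.0 * c
        p = rng.uniform(0.0, 2.0, m)

        new = np.empty_like(pos)
        for i in range(m):
            if abs(k_coef) < 1.0:
                new[i] = successor - z * p[i] * np.abs(k_coef * successor - pos[i])
            elif p[i] < 1.0:
                new[i] = leader - z * p[i] * np.abs(k_coef * leader - pos[i])
            else:
                new[i] = leader - p[i] * np.cos(theta) * np.abs(leader - pos[i])
        pos = objective.clip(new)
        fit = objective.evaluate(pos)
        order = np.argsort(fit, kind="stable")
        if fit[order[0]] < leader_fit:  # elitist leader
            leader_fit = float(fit[order[0]])
            leader = pos[order[0]].copy()
            successor = pos[order[1]].copy()
        else:
            successor = pos[order[0]].copy()
        history.append(objective.external(leader_fit))

    _check_some_finite(leader_fit)
    return OptimizeResult(leader, objective.external(leader_fit), history)


def random_search(
    objective: ObjectiveSpec, n_evaluations: int, seed: int = 0
) -> OptimizeResult:
    """Uniform random search — the budget-matched baseline the population
    optimizers are compared against in tests."""
    rng = np.random.default_rng(seed)
    pos = objective.initial_population(n_evaluations, rng)
    fit = objective.evaluate(pos)
    i = int(np.argmin(fit))
    _check_some_finite(float(fit[i]))
    best = np.minimum.accumulate(fit)
    return OptimizeResult(
        pos[i].copy(),
        objective.external(float(fit[i])),
        [objective.external(float(v)) for v in best],
    )
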