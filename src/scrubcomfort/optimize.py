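"""Particle-swarm search for the most comfortable operating point.

The objective is the squared deviation of modelled comfort from the
ideal value G (default 1):

    G(v, N) = (G - g*(v, N))^2,

minimised over a box of feasible speeds and forces with a standard
inertia-weight PSO.  Because comfort depends on (v, N) only through the
perceived magnitude S(v, N), the minimiser is not a point but the whole
iso-comfort ridge { (v, N) : S(v, N) = S* }; the PSO returns one point
on it, and :func:`extract_iso_comfort_ridge` makes the full set explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .comfort import ComfortParams, comfort_surface, peak_magnitude
from .stevens import psychological_magnitude
from .energy import ScrubCondition

__all__ = [
    "PSOConfig",
    "OptimizationResult",
    "IsoComfortRidge",
    "comfort_objective",
    "pso_minimize",
    "optimize_comfort",
    "extract_iso_comfort_ridge",
]

#: feasible box used for scrubbing optimisation: v in m/s-scaled units, N in newtons
DEFAULT_V_BOUNDS = (0.02, 0.05)
DEFAULT_N_BOUNDS = (0.5, 3.0)
DEFAULT_SEED = 20221104


@dataclass(frozen=True)
class PSOConfig:
    """Hyperparameters of the inertia-weight particle swarm.

    Defaults are the standard constriction-equivalent setting
    (w = 0.729, c1 = c2 = 1.49445) with 40 particles and 200 iterations.
    """

    bounds: tuple[tuple[float, float], ...] = (DEFAULT_V_BOUNDS, DEFAULT_N_BOUNDS)
    swarm_size: int = 40
    max_iter: int = 200
    w: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    tol: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm must have at least 2 particles")
        if not 0 < self.w < 1:
            raise ValueError(f"inertia weight must be in (0, 1), got {self.w}")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("acceleration coefficients must be positive")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds must be finite with lo < hi, got ({lo}, {hi})")


@dataclass(frozen=True)
class OptimizationResult:
    """Best point found, its objective, and the global-best trace."""

    best_pos: np.ndarray
    best_objective: float
    history: tuple[float, ...]
    seed: int
    n_evals: int

    @property
    def best_v(self) -> float:
        """Optimal speed (m/s) — first search dimension."""
        return float(self.best_pos[0])

    @property
    def best_N(self) -> float:
        """Optimal normal force (N) — second search dimension."""
        return float(self.best_pos[1])


@dataclass(frozen=True)
class IsoComfortRidge:
    """Sampled (v, N) pairs with maximal comfort; empty if outside the box."""

    points: tuple[tuple[float, float], ...]
    in_box: bool


def comfort_objective(
    v: float,
    N: float,
    params: ComfortParams | None = None,
    G_target: float = 1.0,
    dt: float = 10.0,
) -> float:
    """Squared comfort deviation (G - g*(v, N))^2."""
    if dt <= 0:
        raise ValueError(f"duration must be positive, got dt={dt}")
    g = comfort_surface(v, N, dt, params or ComfortParams())
    return float((G_target - g) ** 2)


def pso_minimize(objective: Callable[[np.ndarray], float], config: PSOConfig) -> OptimizationResult:
    """Minimise a box-constrained objective with an inertia-weight PSO.

    Velocity update: v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x);
    positions are clipped to the box.  Fully deterministic given the
    config seed.  A NaN objective value aborts with a diagnostic.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    n, d = config.swarm_size, len(config.bounds)

    pos = lo + rng.random((n, d)) * (hi - lo)
    vel = (rng.random((n, d)) - 0.5) * (hi - lo) * 0.1
    n_evals = 0

    def evaluate(points: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        vals = np.array([objective(p) for p in points], dtype=float)
        n_evals += len(points)
        if np.any(np.isnan(vals)):
            bad = points[np.nonzero(np.isnan(vals))[0][0]]
            raise ValueError(f"objective returned NaN at {bad}")
        return vals

    pbest = pos.copy()
    pbest_val = evaluate(pos)
    g_idx = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g_idx].copy(), float(pbest_val[g_idx])
    history = [gbest_val]

    for _ in range(config.max_iter):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        vel = config.w * vel + config.c1 * r1 * (pbest - pos) + config.c2 * r2 * (gbest - pos)
        pos = np.clip(pos + vel, lo, hi)
        vals = evaluate(pos)
        improved = vals < pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = vals[improved]
        g_idx = int(np.argmin(pbest_val))
        if pbest_val[g_idx] < gbest_val:
            gbest, gbest_val = pbest[g_idx].copy(), float(pbest_val[g_idx])
        history.append(gbest_val)
        if config.tol > 0 and gbest_val <= config.tol:
            break

    return OptimizationResult(
        best_pos=gbest, best_objective=gbest_val,
        history=tuple(history), seed=config.seed, n_evals=n_evals,
    )


def optimize_comfort(
    params: ComfortParams | None = None,
    v_bounds: tuple[float, float] = DEFAULT_V_BOUNDS,
    N_bounds: tuple[float, float] = DEFAULT_N_BOUNDS,
    dt: float = 10.0,
    G_target: float = 1.0,
    config: PSOConfig | None = None,
    seed: int | None = None,
) -> OptimizationResult:
    """PSO over the (v, N) box for the comfort-deviation objective."""
    params = params or ComfortParams()
    if config is None:
        config = PSOConfig(bounds=(v_bounds, N_bounds),
                           seed=DEFAULT_SEED if seed is None else seed)
    return pso_minimize(
        lambda p: comfort_objective(p[0], p[1], params, G_target=G_target, dt=dt), config
    )


def extract_iso_comfort_ridge(
    params: ComfortParams | None = None,
    v_bounds: tuple[float, float] = DEFAULT_V_BOUNDS,
    N_bounds: tuple[float, float] = DEFAULT_N_BOUNDS,
    dt: float = 10.0,
    n_points: int = 50,
) -> IsoComfortRidge:
    """Sample the maximal-comfort curve S(v, N) = S* inside the box.

    For each speed on a grid, the force solving the ridge equation is
    found by bracketed root-solving (S is strictly increasing in N).
    Speeds whose ridge force falls outside the force bounds are skipped;
    if no speed admits a solution the ridge misses the box entirely.
    """
    params = params or ComfortParams()
    s_star = peak_magnitude(params.a, params.b)
    points: list[tuple[float, float]] = []

    def s_minus_star(N: float, v: float) -> float:
        cond = ScrubCondition(v=v, N=N, dt=dt)
        return psychological_magnitude(cond, params) - s_star

    for v in np.linspace(v_bounds[0], v_bounds[1], n_points):
        f_lo = s_minus_star(N_bounds[0], v)
        f_hi = s_minus_star(N_bounds[1], v)
        if f_lo > 0 or f_hi < 0:
            continue
        N_root = brentq(s_minus_star, N_bounds[0], N_bounds[1], args=(v,),
                        xtol=1e-14, rtol=8.9e-16)
        points.append((float(v), float(N_root)))

    return IsoComfortRidge(points=tuple(points), in_box=bool(points))
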