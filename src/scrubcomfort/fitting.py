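"""Physics-constrained estimation of the comfort-model parameters.

The sensitivity indices (x, y) and curve shape factors (a, b) are
estimated from observed (N, v, g) triples by nonlinear least squares in
which the model structure itself — the energy-based Stevens composition
feeding the normalised bell curve — is the physics constraint.  The
Stevens and friction constants (k, n, mu, m_exp) stay fixed at their
calibrated values.

Fitting is bounded and multi-started from a Latin-hypercube design to
avoid the shallow local minima of the comfort surface.  Goodness of fit
is reported as SSE and R^2 = 1 - SSE/SST.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .comfort import ComfortParams, comfort_surface
from .energy import ScrubCondition

__all__ = [
    "ComfortObservation",
    "FitResult",
    "DEFAULT_BOUNDS",
    "DEFAULT_SEED",
    "normalize_ratings",
    "goodness_of_fit",
    "fit_comfort_params",
]

logger = logging.getLogger(__name__)

#: default box constraints per free parameter
DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "x": (1e-6, 10.0),
    "y": (1e-6, 10.0),
    "a": (0.5, 3.0),
    "b": (0.5, 4.0),
}

DEFAULT_SEED = 20221104

_FREE_ORDER = ("x", "y", "a", "b")


@dataclass(frozen=True)
class ComfortObservation:
    """One (condition, observed normalized comfort) data point."""

    cond: ScrubCondition
    g_obs: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.g_obs <= 1.0:
            raise ValueError(f"comfort rating must lie in [0, 1], got {self.g_obs}")


@dataclass(frozen=True)
class FitResult:
    params: ComfortParams
    sse: float
    r_squared: float
    n_obs: int
    converged: bool
    n_starts: int
    seed: int
    free: tuple[str, ...] = ()
    per_start_sse: tuple[float, ...] = field(default=(), repr=False)


def normalize_ratings(raw: Sequence[float]) -> np.ndarray:
    """Min-max normalisation of raw comfort scores to [0, 1].

    A constant input carries no ordering information and maps to the
    neutral value 0.5 everywhere.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty list of ratings")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.full_like(arr, 0.5)
    return (arr - lo) / (hi - lo)


def goodness_of_fit(pred: Sequence[float], obs: Sequence[float]) -> tuple[float, float]:
    """(SSE, R^2) of predictions against observations.

    R^2 = 1 - SSE/SST; when the observations have zero variance the SST
    is zero and R^2 is undefined, returned as NaN with a warning.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if o.size < 2:
        raise ValueError("need at least 2 observations")
    sse = float(np.sum((p - o) ** 2))
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("observations have zero variance; R^2 undefined", RuntimeWarning)
        return sse, float("nan")
    return sse, 1.0 - sse / sst


def _pack_arrays(obs: Sequence[ComfortObservation]):
    v = np.array([o.cond.v for o in obs])
    N = np.array([o.cond.N for o in obs])
    dt = np.array([o.cond.dt for o in obs])
    g = np.array([o.g_obs for o in obs])
    return v, N, dt, g


def fit_comfort_params(
    obs: Sequence[ComfortObservation],
    free: Sequence[str] = ("x", "y"),
    params: ComfortParams | None = None,
    init: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int = DEFAULT_SEED,
) -> FitResult:
    """Fit a subset of (x, y, a, b) to observed comfort values.

    Parameters
    ----------
    obs : sequence of ComfortObservation
        The (condition, comfort) data; comfort must already be
        normalised to [0, 1].
    free : sequence of str
        Which of ``x, y, a, b`` to estimate; the rest stay at the
        values in ``params``.
    params : ComfortParams
        Fixed constants and the values of non-free parameters.
    init : mapping, optional
        An explicit starting point, used as the first start.
    bounds : mapping, optional
        Per-parameter (lo, hi) boxes; defaults to :data:`DEFAULT_BOUNDS`.
    n_starts : int
        Number of Latin-hypercube starting points.
    seed : int
        RNG seed for the start design.

    Ties between starts with equal SSE are broken towards the
    lexicographically smallest parameter vector, making the result
    deterministic and order-independent.
    """
    if params is None:
        params = ComfortParams()
    free = tuple(f for f in _FREE_ORDER if f in set(free))
    if len(set(free)) != len([f for f in free]):  # pragma: no cover - defensive
        raise ValueError("duplicate free parameters")
    unknown = set(free) - set(_FREE_ORDER)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    if len(obs) < len(free) + 1:
        raise ValueError(f"need at least {len(free) + 1} observations to fit {free}, have {len(obs)}")

    v, N, dt, g = _pack_arrays(obs)

    if not free:
        pred = comfort_surface(v, N, dt, params)
        sse, r2 = goodness_of_fit(pred, g)
        return FitResult(params=params, sse=sse, r_squared=r2, n_obs=len(obs),
                         converged=True, n_starts=0, seed=seed, free=free)

    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[f][0] for f in free])
    hi = np.array([bnds[f][1] for f in free])
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ValueError("bounds must be finite")

    def residuals(theta: np.ndarray) -> np.ndarray:
        trial = params.with_values(**dict(zip(free, theta)))
        return comfort_surface(v, N, dt, trial) - g

    # Over-sample candidate starts and keep the most promising: the SSE
    # landscape has a wide plateau (large x or y drive the surface to the
    # neutral 0.5), where local search stalls.  Cheap pre-screening by
    # SSE keeps the polished starts inside the informative basin.
    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    candidates = qmc.scale(sampler.random(max(8 * n_starts, 64)), lo, hi)
    cand_sse = np.array([float(np.sum(residuals(c) ** 2)) for c in candidates])
    starts = candidates[np.argsort(cand_sse)[:n_starts]]
    if init is not None:
        x0 = np.array([init.get(f, getattr(params, f)) for f in free])
        starts = np.vstack([np.clip(x0, lo, hi), starts])

    best_theta, best_sse, per_start, any_converged = None, np.inf, [], False
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception as exc:  # numerical failure on one start is not fatal
            logger.debug("start %s failed: %s", x0, exc)
            per_start.append(np.inf)
            continue
        sse = float(2.0 * sol.cost)
        per_start.append(sse)
        any_converged = any_converged or bool(sol.success)
        better = sse < best_sse - 1e-14
        tied = abs(sse - best_sse) <= 1e-14 and best_theta is not None \
            and tuple(sol.x) < tuple(best_theta)
        if best_theta is None or better or tied:
            best_theta, best_sse = sol.x, sse

    if best_theta is None or not any_converged:
        raise RuntimeError(
            f"comfort fit failed to converge across {len(starts)} starts; "
            f"best SSE so far: {best_sse}"
        )

    fitted = params.with_values(**{f: float(t) for f, t in zip(free, best_theta)})
    pred = comfort_surface(v, N, dt, fitted)
    sse, r2 = goodness_of_fit(pred, g)
    return FitResult(
        params=fitted, sse=sse, r_squared=r2, n_obs=len(obs),
        converged=any_converged, n_starts=len(starts), seed=seed,
        free=free, per_start_sse=tuple(per_start),
    )
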