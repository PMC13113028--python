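"""Stevens' psychophysical power law and its log-log fit.

Perceived magnitude S relates to stimulus intensity I through
S = k*(I - I0)**n.  With the absolute threshold I0 at zero (contact is
the only stimulus source here), taking base-10 logarithms linearises
the law, lg S = lg k + n*lg I, so (k, n) are recovered by ordinary
least squares on (lg I, lg S).

The extended condition-level model introduces sensitivity indices x and
y on speed and normal force:

    S = c0 * v**x * N**(m*y) * dt**n,   c0 = k * (4/3 * mu)**n,

with c0 ~ 0.54 for the nylon brush constants (k=2.88, n=1.52, mu=0.25).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .comfort import ComfortParams
    from .energy import ScrubCondition

__all__ = [
    "StevensParams",
    "StimulusResponsePair",
    "PowerLawFit",
    "FittingError",
    "stevens_response",
    "fit_power_law",
    "psychological_magnitude",
]

logger = logging.getLogger(__name__)


class FittingError(ValueError):
    """Raised when a power-law fit cannot be performed."""


@dataclass(frozen=True)
class StevensParams:
    """Power-law constants: scale k, exponent n, absolute threshold I0 (J)."""

    k: float = 2.88
    n: float = 1.52
    I0: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if self.I0 < 0:
            raise ValueError(f"I0 must be non-negative, got {self.I0}")


@dataclass(frozen=True)
class StimulusResponsePair:
    """One (stimulus energy, perceived magnitude) observation."""

    I: float
    S: float


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log regression: parameters plus diagnostics.

    ``slope`` is the power exponent n, ``intercept`` is lg k; ``sse`` and
    ``r_squared`` are computed in log10 space.
    """

    params: StevensParams
    slope: float
    intercept: float
    r_squared: float
    sse: float
    n_used: int
    n_excluded: int


def stevens_response(I, params: StevensParams):
    """Perceived magnitude k*(I - I0)**n; zero at threshold.

    Accepts scalars or arrays; raises on sub-threshold stimuli.
    """
    I_arr = np.asarray(I, dtype=float)
    if np.any(I_arr < params.I0):
        raise ValueError(f"stimulus below absolute threshold I0={params.I0}")
    out = params.k * (I_arr - params.I0) ** params.n
    return out.item() if np.isscalar(I) or I_arr.ndim == 0 else out


def fit_power_law(pairs: Iterable[StimulusResponsePair | tuple[float, float]]) -> PowerLawFit:
    """Fit (k, n) by OLS on base-10 logarithms of stimulus and response.

    Records with non-positive I or S cannot be log-transformed (they
    correspond to "no sensation" ratings, below Stevens' domain) and are
    excluded with a warning.  At least 3 usable pairs are required.
    """
    normalized = [(p.I, p.S) if isinstance(p, StimulusResponsePair) else (float(p[0]), float(p[1]))
                  for p in pairs]
    if not normalized:
        raise FittingError("no stimulus-response pairs given")

    I = np.array([p[0] for p in normalized])
    S = np.array([p[1] for p in normalized])
    usable = (I > 0) & (S > 0)
    excluded = np.nonzero(~usable)[0]
    if excluded.size:
        logger.warning(
            "excluding %d record(s) with non-positive stimulus or response "
            "(indices %s) from log-log fit", excluded.size, excluded.tolist()
        )
    if usable.sum() < 3:
        raise FittingError(
            f"need at least 3 pairs with positive I and S, have {int(usable.sum())} "
            f"(excluded record indices: {excluded.tolist()})"
        )

    log_i = np.log10(I[usable])
    log_s = np.log10(S[usable])
    res = stats.linregress(log_i, log_s)
    resid = log_s - (res.intercept + res.slope * log_i)
    sse = float(np.sum(resid**2))
    return PowerLawFit(
        params=StevensParams(k=10.0**res.intercept, n=res.slope),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        sse=sse,
        n_used=int(usable.sum()),
        n_excluded=int(excluded.size),
    )


def fit_power_law_per_group(
    groups: Sequence[Sequence[StimulusResponsePair | tuple[float, float]]],
) -> PowerLawFit:
    """Average of per-group fits (e.g. per subject).

    The pooled fit (:func:`fit_power_law` on concatenated data) is the
    default elsewhere; this averages slope and intercept across groups
    and rebuilds (k, n) from the means.
    """
    fits = [fit_power_law(g) for g in groups]
    slope = float(np.mean([f.slope for f in fits]))
    intercept = float(np.mean([f.intercept for f in fits]))
    return PowerLawFit(
        params=StevensParams(k=10.0**intercept, n=slope),
        slope=slope,
        intercept=intercept,
        r_squared=float(np.mean([f.r_squared for f in fits])),
        sse=float(np.sum([f.sse for f in fits])),
        n_used=sum(f.n_used for f in fits),
        n_excluded=sum(f.n_excluded for f in fits),
    )


def psychological_magnitude(cond: "ScrubCondition", params: "ComfortParams") -> float:
    """Condition-level perceived magnitude of the extended model.

    S = c0 * v**x * N**(m*y) * dt**n with c0 = k*(4/3*mu)**n; the
    sensitivity indices x and y absorb the outer Stevens exponent, so
    they are not raised to n again.  Speed must be in m/s.
    """
    c0 = params.c0
    return c0 * cond.v**params.x * cond.N ** (params.m_exp * params.y) * cond.dt**params.n
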