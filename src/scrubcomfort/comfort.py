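"""The bell-shaped comfort function and the composed comfort model.

Comfort is not monotone in stimulation: no stimulus leaves a person in a
neutral state, moderate stimulation is pleasant, and excessive
stimulation is unpleasant.  This is captured by a modified-Gaussian
comfort function of the perceived magnitude S,

    g(S) = exp(-pi * |S**b - mu'|**a),

whose two free shape parameters (a, b) control the decay rate of the
curve.  The normalisation constants are not free: demanding that the
maximum of g be exactly 1 and that the no-stimulus baseline g(0) be
exactly 0.5 fixes the spread at sigma = 1/sqrt(2*pi) and the centre at

    mu' = (ln 2 / pi)**(1/a),

because exp(-pi * mu'**a) = exp(-ln 2) = 1/2.  The peak sits at
S* = (ln 2 / pi)**(1/(a*b)).

Composing g with the extended Stevens model of
:func:`scrubcomfort.stevens.psychological_magnitude` gives the
condition-to-comfort map g*(v, N) used for fitting and optimisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .energy import ScrubCondition
from .stevens import psychological_magnitude

__all__ = [
    "ComfortParams",
    "SIGMA",
    "bell_center",
    "peak_magnitude",
    "comfort_gaussian",
    "comfort_function",
    "comfort_from_condition",
    "comfort_surface",
]

#: spread fixed by the max-comfort constraint: 1/sqrt(2*pi)
SIGMA = 1.0 / math.sqrt(2.0 * math.pi)


def bell_center(a: float) -> float:
    """Centre mu' = (ln 2 / pi)**(1/a) fixed by the g(0) = 0.5 constraint."""
    if a <= 0:
        raise ValueError(f"shape parameter a must be positive, got {a}")
    return (math.log(2.0) / math.pi) ** (1.0 / a)


def peak_magnitude(a: float, b: float) -> float:
    """Magnitude S* = (ln 2 / pi)**(1/(a*b)) at which comfort peaks at 1."""
    if a <= 0 or b <= 0:
        raise ValueError("shape parameters must be positive")
    return (math.log(2.0) / math.pi) ** (1.0 / (a * b))


@dataclass(frozen=True)
class ComfortParams:
    """All constants of the condition-to-comfort model.

    Free fields are the Stevens constants (k, n), the friction constants
    (mu, m_exp), the sensitivity indices (x for speed, y for force) and
    the comfort-curve shape factors (a, b).  Defaults are the fitted
    values for forearm scrubbing with a nylon brush.  Derived constants
    (c0, center, sigma, s_peak) are computed, never stored.
    """

    k: float = 2.88
    n: float = 1.52
    mu: float = 0.25
    m_exp: float = 0.7
    x: float = 1.66
    y: float = 3.87
    a: float = 1.04
    b: float = 2.01

    def __post_init__(self) -> None:
        for name in ("k", "n", "mu", "m_exp", "x", "y", "a", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        if self.mu >= 1:
            raise ValueError(f"friction coefficient must be < 1, got mu={self.mu}")

    @property
    def c0(self) -> float:
        """Leading coefficient k*(4/3*mu)**n of the extended model (~0.54)."""
        return self.k * (4.0 / 3.0 * self.mu) ** self.n

    @property
    def center(self) -> float:
        """Comfort-curve centre mu' = (ln 2/pi)**(1/a)."""
        return bell_center(self.a)

    @property
    def sigma(self) -> float:
        return SIGMA

    @property
    def s_peak(self) -> float:
        """Perceived magnitude at which comfort is maximal (= 1)."""
        return peak_magnitude(self.a, self.b)

    def with_values(self, **updates: float) -> "ComfortParams":
        """Copy with some free fields replaced."""
        return replace(self, **updates)


def comfort_gaussian(S, sigma: float = SIGMA, center: float = 0.0):
    """Plain normal density in S; peak 1/(sigma*sqrt(2*pi)) at the centre.

    With the model's sigma = 1/sqrt(2*pi) the peak value is exactly 1.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    S_arr = np.asarray(S, dtype=float)
    out = np.exp(-((S_arr - center) ** 2) / (2.0 * sigma**2)) / (sigma * math.sqrt(2.0 * math.pi))
    return out.item() if np.isscalar(S) or S_arr.ndim == 0 else out


def comfort_function(S, a: float = 1.04, b: float = 2.01):
    """Comfort g(S) = exp(-pi*|S**b - mu'|**a) in (0, 1].

    Exactly 0.5 at S = 0, exactly 1 at S* = (ln 2/pi)**(1/(a*b)), and
    decaying to 0 for large S.  The absolute value makes the fractional
    power a real, sign-symmetric decay on both sides of the peak.
    """
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValueError("perceived magnitude S must be non-negative")
    mu_p = bell_center(a)
    if b <= 0:
        raise ValueError(f"shape parameter b must be positive, got {b}")
    out = np.exp(-math.pi * np.abs(S_arr**b - mu_p) ** a)
    return out.item() if np.isscalar(S) or S_arr.ndim == 0 else out


def comfort_from_condition(cond: ScrubCondition, params: ComfortParams | None = None) -> float:
    """Comfort of one operating point: g(S(v, N, dt))."""
    if params is None:
        params = ComfortParams()
    return comfort_function(psychological_magnitude(cond, params), params.a, params.b)


def comfort_surface(v, N, dt: float = 10.0, params: ComfortParams | None = None):
    """Vectorised comfort over arrays of speed (m/s) and force (N).

    Broadcasts v against N; used by the fitting and optimisation layers
    where per-condition object construction would dominate runtime.
    """
    if params is None:
        params = ComfortParams()
    v_arr = np.asarray(v, dtype=float)
    N_arr = np.asarray(N, dtype=float)
    if np.any(v_arr < 0) or np.any(N_arr < 0):
        raise ValueError("speed and force must be non-negative")
    S = params.c0 * v_arr**params.x * N_arr ** (params.m_exp * params.y) * dt**params.n
    return comfort_function(S, params.a, params.b)
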