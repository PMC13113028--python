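"""Mechanical energy transferred from a scrubbing end to the skin.

The stimulus driving the comfort model is the energy a rotating,
translating brush delivers during a stroke: friction work from the
translational and rotational motion plus the (small) elastic energy
stored in normal and tangential skin deformation.

Skin friction does not follow Amontons' law.  Following the tribology of
soft tissue, the tangential force grows as a power of the normal load,

    f = mu * N**m,    m ~ 0.67-0.72 (default 0.7),

and the total energy over a stroke of duration ``dt`` decomposes as

    E = E_t + E_r + E_sigma + E_tau
      = f*v1*dt + (2/3)*f*r*omega*dt + N^2*l/(2*Y1*A) + f^2*l/(A*Y2).

When the rim speed of the brush equals the translational speed
(v2 = r*omega = v1 = v) and deformation terms are dropped, this collapses
to the simplified stimulus used throughout the model:

    E = (4/3) * v * mu * N**m * dt.

All quantities are SI internally (m, m/s, s, N, Pa, J).  User-facing
files and CLI flags use mm/s for speed; conversion happens once at the
I/O boundary (see :mod:`scrubcomfort.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ScrubCondition",
    "SkinProperties",
    "EnergyBreakdown",
    "friction_force",
    "rotational_energy_per_rev",
    "deformation_energies",
    "total_energy_full",
    "total_energy_simplified",
]

#: friction coefficient of the nylon brush head against skin
DEFAULT_MU = 0.25
#: load exponent of the skin friction power law
DEFAULT_M_EXP = 0.7
#: brush radius in metres
DEFAULT_RADIUS = 0.05


@dataclass(frozen=True)
class ScrubCondition:
    """One operating point of the scrubbing end.

    Parameters
    ----------
    v : float
        Translational speed in m/s (use :meth:`from_mm_s` for mm/s input).
    N : float
        Normal contact force in newtons.
    dt : float
        Stroke duration in seconds.
    mu : float
        Skin-brush friction coefficient.
    m_exp : float
        Load exponent of the friction power law.
    r : float
        Brush radius in metres.
    omega : float or None
        Rotational speed in rad/s.  ``None`` selects the default
        convention that the rim speed equals the translational speed,
        i.e. ``omega = v / r``.
    dS : float or None
        Translational displacement in metres; derived as ``v * dt``
        when not given.
    """

    v: float
    N: float
    dt: float
    mu: float = DEFAULT_MU
    m_exp: float = DEFAULT_M_EXP
    r: float = DEFAULT_RADIUS
    omega: float | None = None
    dS: float | None = None

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError(f"speed must be non-negative, got v={self.v}")
        if self.N < 0:
            raise ValueError(f"normal force must be non-negative, got N={self.N}")
        if self.dt <= 0:
            raise ValueError(f"duration must be positive, got dt={self.dt}")
        if not 0 < self.mu < 1:
            raise ValueError(f"friction coefficient must be in (0, 1), got mu={self.mu}")
        if not 0 < self.m_exp <= 1:
            raise ValueError(f"load exponent must be in (0, 1], got m_exp={self.m_exp}")
        if self.r <= 0:
            raise ValueError(f"brush radius must be positive, got r={self.r}")
        if self.omega is not None and self.omega < 0:
            raise ValueError(f"rotational speed must be non-negative, got omega={self.omega}")

    @classmethod
    def from_mm_s(cls, v_mm_s: float, N: float, dt: float, **kwargs) -> "ScrubCondition":
        """Build a condition from a user-facing speed in mm/s."""
        return cls(v=v_mm_s / 1000.0, N=N, dt=dt, **kwargs)

    @property
    def v_mm_s(self) -> float:
        return self.v * 1000.0

    @property
    def effective_omega(self) -> float:
        """Rotational speed actually used: v/r when omega is unset."""
        return self.v / self.r if self.omega is None else self.omega

    @property
    def displacement(self) -> float:
        return self.v * self.dt if self.dS is None else self.dS


@dataclass(frozen=True)
class SkinProperties:
    """Elastic skin parameters entering the deformation energies.

    ``l`` is the combined skin/muscle tissue thickness (m), ``Y1`` and
    ``Y2`` the normal and tangential elastic moduli (Pa), and ``A`` the
    contact area (m^2), by default the full brush footprint pi*r^2.
    """

    l: float = 0.008
    Y1: float = 1.0e5
    Y2: float = 5.0e4
    A: float = field(default=math.pi * DEFAULT_RADIUS**2)

    def __post_init__(self) -> None:
        for name in ("l", "Y1", "Y2", "A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"skin property {name} must be strictly positive")

    @classmethod
    def from_radius(cls, r: float, **kwargs) -> "SkinProperties":
        return cls(A=math.pi * r**2, **kwargs)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy components (J) of one stroke.

    ``Ef = Et + Er`` and ``E = Ef + Esigma + Etau`` hold by construction.
    """

    Et: float
    Er: float
    Esigma: float
    Etau: float

    @property
    def Ef(self) -> float:
        return self.Et + self.Er

    @property
    def E(self) -> float:
        return self.Ef + self.Esigma + self.Etau


def friction_force(N: float, mu: float = DEFAULT_MU, m_exp: float = DEFAULT_M_EXP) -> float:
    """Skin friction force f = mu * N**m_exp (N)."""
    if N < 0:
        raise ValueError(f"normal force must be non-negative, got N={N}")
    if mu <= 0:
        raise ValueError(f"friction coefficient must be positive, got mu={mu}")
    return mu * N**m_exp


def rotational_energy_per_rev(f: float, r: float) -> float:
    """Friction work of one full brush revolution, (4/3)*pi*f*r (J)."""
    if f < 0:
        raise ValueError(f"friction force must be non-negative, got f={f}")
    if r <= 0:
        raise ValueError(f"radius must be positive, got r={r}")
    return (4.0 / 3.0) * math.pi * f * r


def deformation_energies(N: float, f: float, skin: SkinProperties) -> tuple[float, float]:
    """Elastic energies of normal and tangential skin deformation.

    Returns ``(Esigma, Etau)`` with ``Esigma = N^2*l/(2*Y1*A)`` and
    ``Etau = f^2*l/(A*Y2)``.
    """
    if N < 0 or f < 0:
        raise ValueError("forces must be non-negative")
    e_sigma = N**2 * skin.l / (2.0 * skin.Y1 * skin.A)
    e_tau = f**2 * skin.l / (skin.A * skin.Y2)
    return e_sigma, e_tau


def total_energy_full(cond: ScrubCondition, skin: SkinProperties | None = None) -> EnergyBreakdown:
    """Full per-stroke energy budget.

    Et = f*v*dt (translation), Er = (2/3)*f*r*omega*dt (rotation over
    ``omega*dt/(2*pi)`` revolutions), plus both deformation terms.
    """
    if skin is None:
        skin = SkinProperties.from_radius(cond.r)
    f = friction_force(cond.N, cond.mu, cond.m_exp)
    et = f * cond.displacement
    er = (2.0 / 3.0) * f * cond.r * cond.effective_omega * cond.dt
    e_sigma, e_tau = deformation_energies(cond.N, f, skin)
    return EnergyBreakdown(Et=et, Er=er, Esigma=e_sigma, Etau=e_tau)


def total_energy_simplified(cond: ScrubCondition) -> float:
    """Simplified stimulus energy E = (4/3)*v*mu*N**m*dt (J).

    Assumes the brush rim speed equals the translational speed and drops
    the deformation terms, which are negligible for elastic skin at the
    forces considered.
    """
    f = friction_force(cond.N, cond.mu, cond.m_exp)
    return (4.0 / 3.0) * cond.v * f * cond.dt
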