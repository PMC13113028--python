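"""Synthetic data with known ground truth for every pipeline stage.

Three generators mirror the three kinds of input the pipeline consumes:

* VAS rating tables over the Stevens calibration grid (8 forces x
  8 speeds, 10 s strokes — 64 conditions), generated from the power law
  applied to the simplified stimulus energy;
* comfort surfaces over the comfort-calibration grid (6 forces x
  7 speeds, 42 conditions), generated from the full condition-to-comfort
  model;
* RR-interval series with controllable SDNN and LF/HF content, built
  from sinusoidal modulation at the LF and HF band centres (0.1 and
  0.25 Hz) plus white noise.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .comfort import ComfortParams, comfort_from_condition
from .energy import ScrubCondition, total_energy_simplified
from .fitting import ComfortObservation
from .hrv import RRSeries
from .stevens import StevensParams, stevens_response

__all__ = [
    "GeneratorSpec",
    "STEVENS_GRID_FORCES",
    "STEVENS_GRID_SPEEDS_MM_S",
    "COMFORT_GRID_FORCES",
    "COMFORT_GRID_SPEEDS_MM_S",
    "stevens_grid",
    "comfort_grid",
    "generate_vas_ratings",
    "generate_comfort_surface",
    "generate_rr_series",
]

#: Stevens-calibration design: 8 forces (N) x 8 speeds (mm/s), 10 s strokes
STEVENS_GRID_FORCES = (0.1, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
STEVENS_GRID_SPEEDS_MM_S = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

#: comfort-calibration design: 6 forces (N) x 7 speeds (mm/s)
COMFORT_GRID_FORCES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
COMFORT_GRID_SPEEDS_MM_S = (20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)

DEFAULT_SEED = 20221104


def stevens_grid(dt: float = 10.0) -> list[ScrubCondition]:
    """The 64-condition Stevens calibration design."""
    return [
        ScrubCondition.from_mm_s(v, N, dt)
        for N in STEVENS_GRID_FORCES
        for v in STEVENS_GRID_SPEEDS_MM_S
    ]


def comfort_grid(dt: float = 10.0) -> list[ScrubCondition]:
    """The 42-condition comfort calibration design."""
    return [
        ScrubCondition.from_mm_s(v, N, dt)
        for N in COMFORT_GRID_FORCES
        for v in COMFORT_GRID_SPEEDS_MM_S
    ]


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth and noise level for the rating/surface generators.

    ``noise_sd`` is on the normalized comfort scale [0, 1]; the VAS
    generator applies it x10 on the 0-10 scale.  ``vas_resolution`` is
    the rounding step of the rating marks.
    """

    grid: tuple[ScrubCondition, ...] = field(default_factory=lambda: tuple(stevens_grid()))
    true_params: ComfortParams = field(default_factory=ComfortParams)
    noise_sd: float = 0.05
    vas_resolution: float = 0.1
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.vas_resolution <= 0:
            raise ValueError("vas_resolution must be positive")
        if not self.grid:
            raise ValueError("grid must be non-empty")


def generate_vas_ratings(spec: GeneratorSpec) -> list[dict]:
    """Simulated VAS ratings over the spec's condition grid.

    The noiseless rating is the Stevens response to the simplified
    stimulus energy, rescaled so the strongest condition marks 10 on
    the scale; Gaussian noise (sd = 10*noise_sd) is added, the result
    clipped to [0, 10] and rounded to the VAS resolution.

    Returns one record per condition with keys ``id, v_mm_s, N_newton,
    dt_s, vas_raw, s_true``.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.true_params
    sp = StevensParams(k=p.k, n=p.n)
    energies = np.array([total_energy_simplified(c) for c in spec.grid])
    s_true = stevens_response(energies, sp)
    vas = 10.0 * s_true / s_true.max()
    vas = vas + rng.normal(0.0, 10.0 * spec.noise_sd, size=vas.shape)
    vas = np.clip(vas, 0.0, 10.0)
    vas = np.round(vas / spec.vas_resolution) * spec.vas_resolution
    return [
        {
            "id": i,
            "v_mm_s": c.v_mm_s,
            "N_newton": c.N,
            "dt_s": c.dt,
            "vas_raw": float(vas[i]),
            "s_true": float(s_true[i]),
        }
        for i, c in enumerate(spec.grid)
    ]


def generate_comfort_surface(spec: GeneratorSpec | None = None) -> list[ComfortObservation]:
    """Simulated (condition, comfort) observations from the true model.

    g_obs = clip(g*(v, N) + Normal(0, noise_sd), 0, 1) per condition.
    """
    if spec is None:
        spec = GeneratorSpec(grid=tuple(comfort_grid()))
    rng = np.random.default_rng(spec.seed)
    g_true = np.array([comfort_from_condition(c, spec.true_params) for c in spec.grid])
    g_obs = np.clip(g_true + rng.normal(0.0, spec.noise_sd, size=g_true.shape), 0.0, 1.0)
    return [ComfortObservation(cond=c, g_obs=float(g)) for c, g in zip(spec.grid, g_obs)]


def generate_rr_series(
    duration_s: float = 300.0,
    mean_rr_ms: float = 800.0,
    sdnn_target_ms: float = 50.0,
    lf_hf_ratio: float = 2.0,
    seed: int = DEFAULT_SEED,
    noise_frac: float = 0.1,
) -> RRSeries:
    """RR series with sinusoidal LF/HF modulation and white noise.

    Each interval is mean_rr + A_lf*sin(2*pi*0.1*t) +
    A_hf*sin(2*pi*0.25*t) + Normal noise, with beat times accumulating
    until the requested duration is filled.  Amplitudes are chosen so
    the total variance matches sdnn_target^2 (a ``noise_frac`` share
    goes to the white-noise term) and the LF/HF sinusoid variances have
    the requested ratio.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not 300.0 < mean_rr_ms < 1500.0:
        raise ValueError(f"mean RR must lie in (300, 1500) ms, got {mean_rr_ms}")
    if sdnn_target_ms < 0 or lf_hf_ratio <= 0 or not 0 <= noise_frac < 1:
        raise ValueError("infeasible variability targets")

    var_total = sdnn_target_ms**2
    var_noise = noise_frac * var_total
    var_osc = var_total - var_noise
    var_lf = var_osc * lf_hf_ratio / (1.0 + lf_hf_ratio)
    var_hf = var_osc / (1.0 + lf_hf_ratio)
    a_lf = np.sqrt(2.0 * var_lf)
    a_hf = np.sqrt(2.0 * var_hf)
    noise_sd = np.sqrt(var_noise)
    if a_lf + a_hf + 4.0 * noise_sd >= mean_rr_ms:
        raise ValueError("infeasible targets: modulation amplitude exceeds the mean RR")

    rng = np.random.default_rng(seed)
    t = 0.0
    intervals: list[float] = []
    while True:
        rr = (
            mean_rr_ms
            + a_lf * np.sin(2.0 * np.pi * 0.1 * t)
            + a_hf * np.sin(2.0 * np.pi * 0.25 * t)
            + rng.normal(0.0, noise_sd)
        )
        rr = max(rr, 200.0)  # physiological floor; unreachable for feasible targets
        if t + rr / 1000.0 > duration_s:
            break
        intervals.append(rr)
        t += rr / 1000.0
    if len(intervals) < 2:
        raise ValueError("duration too short for the requested mean RR")
    return RRSeries(np.array(intervals))
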