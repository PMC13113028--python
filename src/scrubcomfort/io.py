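"""File schemas: CSV data tables, JSON parameter/result blobs, RR text.

Speeds in every user-facing file are mm/s and converted once, here, to
the model's internal m/s.  Parameter JSON carries only the eight free
fields of :class:`~scrubcomfort.comfort.ComfortParams`; derived
constants are always recomputed, never read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .comfort import ComfortParams
from .energy import ScrubCondition
from .fitting import ComfortObservation
from .hrv import RRSeries
from .stevens import StimulusResponsePair

__all__ = [
    "read_conditions_csv",
    "write_conditions_csv",
    "read_ratings_csv",
    "write_ratings_csv",
    "read_observations_csv",
    "write_observations_csv",
    "read_rr_text",
    "write_rr_text",
    "load_params_json",
    "save_params_json",
    "save_json",
]

_PARAM_FIELDS = ("k", "n", "mu", "m_exp", "x", "y", "a", "b")
_COND_OPTIONAL = ("mu", "m_exp", "r")


def _conditions_from_frame(df: pd.DataFrame) -> list[ScrubCondition]:
    conds = []
    for _, row in df.iterrows():
        extra = {c if c != "r_m" else "r": float(row[c])
                 for c in ("mu", "m_exp", "r_m") if c in df.columns and pd.notna(row[c])}
        conds.append(ScrubCondition.from_mm_s(
            float(row["v_mm_s"]), float(row["N_newton"]), float(row["dt_s"]), **extra))
    return conds


def read_conditions_csv(path: str | Path) -> list[ScrubCondition]:
    """Read a conditions table: columns id, v_mm_s, N_newton, dt_s
    (optional mu, m_exp, r_m)."""
    return _conditions_from_frame(pd.read_csv(path))


def write_conditions_csv(conds: Sequence[ScrubCondition], path: str | Path) -> None:
    pd.DataFrame({
        "id": range(len(conds)),
        "v_mm_s": [c.v_mm_s for c in conds],
        "N_newton": [c.N for c in conds],
        "dt_s": [c.dt for c in conds],
        "mu": [c.mu for c in conds],
        "m_exp": [c.m_exp for c in conds],
        "r_m": [c.r for c in conds],
    }).to_csv(path, index=False)


def read_ratings_csv(path: str | Path) -> tuple[list[ScrubCondition], np.ndarray]:
    """Read a VAS ratings table (id, v_mm_s, N_newton, dt_s, vas_raw).

    Returns the conditions and the raw 0-10 scores.
    """
    df = pd.read_csv(path)
    return _conditions_from_frame(df), df["vas_raw"].to_numpy(dtype=float)


def write_ratings_csv(records: Sequence[dict], path: str | Path) -> None:
    """Write generator output (see synthetic.generate_vas_ratings)."""
    cols = ["id", "v_mm_s", "N_newton", "dt_s", "vas_raw"]
    pd.DataFrame(records)[cols].to_csv(path, index=False)


def ratings_to_pairs(
    conds: Sequence[ScrubCondition], vas_raw: np.ndarray
) -> list[StimulusResponsePair]:
    """Pair each condition's simplified stimulus energy with its
    normalized response (raw VAS / 10)."""
    from .energy import total_energy_simplified

    return [
        StimulusResponsePair(I=total_energy_simplified(c), S=float(s) / 10.0)
        for c, s in zip(conds, vas_raw)
    ]


def read_observations_csv(path: str | Path) -> list[ComfortObservation]:
    """Read comfort observations (id, v_mm_s, N_newton, dt_s, g_obs)."""
    df = pd.read_csv(path)
    conds = _conditions_from_frame(df)
    return [ComfortObservation(cond=c, g_obs=float(g))
            for c, g in zip(conds, df["g_obs"].to_numpy(dtype=float))]


def write_observations_csv(obs: Sequence[ComfortObservation], path: str | Path) -> None:
    pd.DataFrame({
        "id": range(len(obs)),
        "v_mm_s": [o.cond.v_mm_s for o in obs],
        "N_newton": [o.cond.N for o in obs],
        "dt_s": [o.cond.dt for o in obs],
        "g_obs": [o.g_obs for o in obs],
    }).to_csv(path, index=False)


def read_rr_text(path: str | Path) -> RRSeries:
    """Read RR intervals: one value (ms) per line, or CSV with a
    ``rr_ms`` column."""
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0] if path.read_text().strip() else ""
    if "," in first or "rr_ms" in first:
        df = pd.read_csv(path)
        return RRSeries(df["rr_ms"].to_numpy(dtype=float))
    return RRSeries(np.loadtxt(path, dtype=float))


def write_rr_text(rr: RRSeries, path: str | Path) -> None:
    np.savetxt(path, rr.intervals, fmt="%.6f")


def load_params_json(path: str | Path) -> ComfortParams:
    """Load comfort-model parameters; derived fields are recomputed and
    any present in the file are ignored."""
    with open(path) as fh:
        blob = json.load(fh)
    return ComfortParams(**{f: float(blob[f]) for f in _PARAM_FIELDS if f in blob})


def save_params_json(params: ComfortParams, path: str | Path) -> None:
    blob = {f: getattr(params, f) for f in _PARAM_FIELDS}
    blob.update({"c0": params.c0, "center": params.center,
                 "sigma": params.sigma, "s_peak": params.s_peak})
    save_json(blob, path)


def save_json(obj, path: str | Path) -> None:
    """Write any result object (dataclasses and numpy types handled)."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
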