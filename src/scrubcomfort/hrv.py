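"""Heart-rate-variability metrics from RR-interval series.

Six statistics commonly used to index autonomic balance during tactile
stimulation:

* SDNN — standard deviation of all normal-to-normal intervals (ms);
* RMSSD — root mean square of successive differences (ms);
* pNN50 — percentage of successive differences exceeding 50 ms;
* LFnorm, HFnorm — low- (0.04–0.15 Hz) and high-frequency (0.15–0.40 Hz)
  band power as a percentage of their sum;
* LF/HF — the band-power ratio.

Spectral estimation follows the HRV Task-Force convention: the unevenly
sampled RR tachogram is resampled to an even 4 Hz grid by cubic-spline
interpolation and the power spectral density is estimated by Welch's
method (120 s segments, 50% overlap by default), with band powers
obtained by trapezoidal integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

__all__ = [
    "RRSeries",
    "HRVMetrics",
    "LF_BAND",
    "HF_BAND",
    "time_domain_metrics",
    "frequency_domain_metrics",
    "hrv_metrics",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
RESAMPLE_HZ = 4.0
WELCH_SEGMENT_S = 120.0


@dataclass(frozen=True)
class RRSeries:
    """A sequence of normal-to-normal RR intervals in milliseconds."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", arr)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("need a 1-D series of at least 2 RR intervals")
        if np.any(arr <= 0):
            raise ValueError("RR intervals must be strictly positive")

    @property
    def times_s(self) -> np.ndarray:
        """Beat times (s): cumulative sum of the intervals."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1])


@dataclass(frozen=True)
class HRVMetrics:
    sdnn: float
    rmssd: float
    pnn50: float
    lf_power: float
    hf_power: float
    lfnorm: float
    hfnorm: float
    lf_hf: float


def time_domain_metrics(rr: RRSeries, ddof: int = 0) -> tuple[float, float, float]:
    """(SDNN, RMSSD, pNN50) of an RR series.

    SDNN uses the population (n) denominator by default; pass
    ``ddof=1`` for the sample convention.  pNN50 counts successive
    differences strictly greater than 50 ms.
    """
    x = rr.intervals
    sdnn = float(np.std(x, ddof=ddof))
    diff = np.diff(x)
    rmssd = float(np.sqrt(np.mean(diff**2)))
    pnn50 = float(100.0 * np.mean(np.abs(diff) > 50.0))
    return sdnn, rmssd, pnn50


def frequency_domain_metrics(
    rr: RRSeries,
    fs: float = RESAMPLE_HZ,
    segment_s: float = WELCH_SEGMENT_S,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
) -> tuple[float, float, float, float, float]:
    """(LF power, HF power, LFnorm, HFnorm, LF/HF) of an RR series.

    Requires at least 60 s of data.  Powers are in ms^2; the normalized
    powers always sum to 100.  An HF power of zero leaves the ratio
    undefined (NaN, with a warning).
    """
    t = rr.times_s
    if t[-1] - t[0] < 60.0:
        raise ValueError(f"need at least 60 s of RR data, have {t[-1] - t[0]:.1f} s")

    spline = CubicSpline(t, rr.intervals)
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    x = spline(grid)

    nperseg = min(len(x), int(segment_s * fs))
    freqs, psd = welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2,
                       detrend="constant")

    def band_power(band: tuple[float, float]) -> float:
        mask = (freqs >= band[0]) & (freqs <= band[1])
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    lf = band_power(lf_band)
    hf = band_power(hf_band)
    total = lf + hf
    if total == 0.0:
        warnings.warn("no power in LF or HF band; normalized powers undefined", RuntimeWarning)
        return lf, hf, float("nan"), float("nan"), float("nan")
    lfnorm = 100.0 * lf / total
    hfnorm = 100.0 * hf / total
    if hf == 0.0:
        warnings.warn("HF power is zero; LF/HF ratio undefined", RuntimeWarning)
        return lf, hf, lfnorm, hfnorm, float("nan")
    return lf, hf, lfnorm, hfnorm, lf / hf


def hrv_metrics(rr: RRSeries, **freq_kwargs) -> HRVMetrics:
    """All six HRV statistics in one container."""
    sdnn, rmssd, pnn50 = time_domain_metrics(rr)
    lf, hf, lfnorm, hfnorm, lf_hf = frequency_domain_metrics(rr, **freq_kwargs)
    return HRVMetrics(sdnn=sdnn, rmssd=rmssd, pnn50=pnn50,
                      lf_power=lf, hf_power=hf,
                      lfnorm=lfnorm, hfnorm=hfnorm, lf_hf=lf_hf)
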