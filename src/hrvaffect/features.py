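"""The twelve ultra-short-term HRV measures computed on one analysis window.

Time domain: MeanNN, MedianNN, MadNN, SDNN, RMSSD, SDSD, Prc80NN, Prc20NN,
pNN20, pNN50 (all on the window's R-R intervals in ms).  Frequency domain:
absolute high-frequency power HF (0.15-0.4 Hz, ms^2) and its normalized form
HFn = HF / power(0.04-0.4 Hz), from a Welch PSD of the cubic-interpolated,
mean-removed tachogram on a uniform 4 Hz grid.

Conventions (configurable where noted): MadNN carries the 1.4826
normal-consistency constant; pNN thresholds are strict ``>`` on |successive
difference|; percentiles use linear interpolation; SDNN/SDSD use the n-1
sample denominator.  Windows shorter than 120 s carry a low-reliability flag
on the spectral features, whose band resolution is marginal at 55 s.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .core import FEATURE_NAMES, BeatSeries

__all__ = ["FeatureVector", "time_domain", "frequency_domain", "extract_features"]

MAD_CONSISTENCY = 1.4826

HF_BAND = (0.15, 0.4)
TOTAL_BAND = (0.04, 0.4)
INTERP_FS = 4.0          # Hz, uniform tachogram grid
MIN_SPAN_S = 30.0
MIN_INTERVALS_FREQ = 10
RELIABLE_SPAN_S = 120.0


@dataclass(frozen=True)
class FeatureVector:
    """The twelve HRV measures for one window, plus bookkeeping flags."""

    MeanNN: float = np.nan
    MedianNN: float = np.nan
    MadNN: float = np.nan
    SDNN: float = np.nan
    RMSSD: float = np.nan
    SDSD: float = np.nan
    Prc80NN: float = np.nan
    Prc20NN: float = np.nan
    pNN20: float = np.nan
    pNN50: float = np.nan
    HF: float = np.nan
    HFn: float = np.nan
    n_intervals: int = 0
    window_id: str | None = None
    valid: bool = True
    hf_degenerate: bool = False
    hf_low_reliability: bool = False

    @classmethod
    def invalid(cls, window_id: str | None = None, n_intervals: int = 0) -> "FeatureVector":
        """Explicit missing-window marker (never silently zero)."""
        return cls(window_id=window_id, n_intervals=n_intervals, valid=False)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def time_domain(rr: np.ndarray, mad_consistency: bool = True) -> dict[str, float]:
    """The ten time-domain measures of an R-R interval series (ms)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 4:
        raise ValueError(f"need at least 4 intervals (got {rr.size})")
    if np.any(rr <= 0):
        raise ValueError("R-R intervals must be positive")
    d = np.diff(rr)
    med = float(np.median(rr))
    mad = float(np.median(np.abs(rr - med)))
    return {
        "MeanNN": float(np.mean(rr)),
        "MedianNN": med,
        "MadNN": mad * (MAD_CONSISTENCY if mad_consistency else 1.0),
        "SDNN": float(np.std(rr, ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(d ** 2))),
        "SDSD": float(np.std(d, ddof=1)),
        "Prc80NN": float(np.percentile(rr, 80)),
        "Prc20NN": float(np.percentile(rr, 20)),
        "pNN20": 100.0 * float(np.mean(np.abs(d) > 20.0)),
        "pNN50": 100.0 * float(np.mean(np.abs(d) > 50.0)),
    }


def frequency_domain(rr: np.ndarray, beat_times: np.ndarray
                     ) -> tuple[float, float, dict[str, bool]]:
    """HF power (ms^2) and normalized HF of one window's tachogram.

    ``beat_times`` are the *terminating* beat times (s) of the intervals in
    ``rr``.  The tachogram is cubic-interpolated onto a uniform 4 Hz grid,
    mean-removed, and a Welch PSD with a single full-window Hann segment is
    integrated over the HF band; HFn divides by the 0.04-0.4 Hz power.

    Returns ``(HF, HFn, flags)`` where flags mark a zero-variance
    (degenerate) window and sub-120-s low spectral reliability.
    """
    rr = np.asarray(rr, dtype=float)
    beat_times = np.asarray(beat_times, dtype=float)
    if rr.size != beat_times.size:
        raise ValueError("rr and beat_times must have equal length")
    if rr.size < MIN_INTERVALS_FREQ:
        raise ValueError(f"need at least {MIN_INTERVALS_FREQ} intervals")
    span = beat_times[-1] - beat_times[0]
    if span < MIN_SPAN_S:
        raise ValueError(f"window span {span:.1f} s too short (>= {MIN_SPAN_S} s)")

    flags = {"degenerate": False,
             "low_reliability": span < RELIABLE_SPAN_S}
    if np.ptp(rr) == 0.0:
        flags["degenerate"] = True
        return 0.0, 0.0, flags

    grid = np.arange(beat_times[0], beat_times[-1], 1.0 / INTERP_FS)
    tach = CubicSpline(beat_times, rr)(grid)
    tach = tach - tach.mean()
    freqs, psd = sps.welch(tach, fs=INTERP_FS, window="hann",
                           nperseg=tach.size, detrend=False)

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    hf = band_power(*HF_BAND)
    total = band_power(*TOTAL_BAND)
    if total <= 0.0:
        flags["degenerate"] = True
        return hf, 0.0, flags
    return hf, hf / total, flags


def extract_features(beats: BeatSeries, window: tuple[float, float],
                     window_id: str | None = None,
                     mad_consistency: bool = True) -> FeatureVector:
    """One :class:`FeatureVector` for the half-open window ``[start, end)``.

    An interval belongs to the window in which its *terminating* beat falls,
    so each interval is assigned to exactly one contiguous window.  Windows
    with fewer than 4 qualifying intervals are returned as explicit invalid
    markers; spectral features that cannot be computed (short span, too few
    intervals) are NaN with the window otherwise valid.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    term_times = beats.r_times[1:]
    mask = (term_times >= start) & (term_times < end)
    n = int(mask.sum())
    if n < 4:
        return FeatureVector.invalid(window_id=window_id, n_intervals=n)
    rr = beats.rr[mask]
    tt = term_times[mask]
    td = time_domain(rr, mad_consistency=mad_consistency)
    hf, hfn = np.nan, np.nan
    flags = {"degenerate": False, "low_reliability": False}
    try:
        hf, hfn, flags = frequency_domain(rr, tt)
    except ValueError:
        flags = {"degenerate": True, "low_reliability": True}
    return FeatureVector(**td, HF=hf, HFn=hfn, n_intervals=n,
                         window_id=window_id, valid=True,
                         hf_degenerate=flags["degenerate"],
                         hf_low_reliability=flags["low_reliability"])
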