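"""Core data containers shared by the simulation and analysis stages.

The containers mirror the experimental design: a single-lead ECG trace
(:class:`ECGRecord`), the R-peak / R-R interval series derived from it
(:class:`BeatSeries`), and the block-design session timeline of baseline,
stimulus and rest periods (:class:`SessionProtocol`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

GROUPS = ("HC", "MCS", "UWS")
CONDITIONS = ("acquaintance", "stranger")

#: Beat annotation flags.
NORMAL = "normal"
ECTOPIC = "ectopic"
INTERPOLATED = "interpolated"

#: The twelve ultra-short-term HRV measures, in canonical reporting order.
#: These names are the row keys of every downstream feature / results table.
FEATURE_NAMES = (
    "MeanNN", "MedianNN", "MadNN", "SDNN", "RMSSD", "SDSD",
    "Prc80NN", "Prc20NN", "pNN20", "pNN50", "HF", "HFn",
)


class HRVError(Exception):
    """Base class for domain errors raised by this package."""


class UncorrectableSeriesError(HRVError):
    """Raised when the ectopic-beat fraction reaches the exclusion threshold.

    Mirrors the study rule that interpolation is only applied when ectopic
    beats account for less than ``max_fraction`` (default 20%) of all beats;
    noisier series are excluded from analysis rather than corrected.
    """

    def __init__(self, fraction: float, max_fraction: float):
        self.fraction = float(fraction)
        self.max_fraction = float(max_fraction)
        super().__init__(
            f"uncorrectable series: ectopic fraction {fraction:.3f} >= "
            f"threshold {max_fraction:.3f}"
        )


class DetectionError(HRVError):
    """Raised when R-peak detection cannot produce a usable beat series."""


@dataclass(frozen=True)
class ECGRecord:
    """A sampled single-lead voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in millivolts.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds (protocol clock).
    label : str
        Channel name.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = "ECG"

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "ECGRecord":
        return replace(self, samples=samples, fs=self.fs if fs is None else fs)


@dataclass(frozen=True)
class BeatSeries:
    """R-peak times with per-beat annotations.

    ``rr`` (successive differences in ms, length ``n_beats - 1``) is derived,
    never stored, so it can never disagree with the peak times.
    """

    r_times: np.ndarray
    annotations: tuple[str, ...] = ()

    def __post_init__(self):
        times = np.asarray(self.r_times, dtype=float)
        object.__setattr__(self, "r_times", times)
        if times.ndim != 1:
            raise ValueError("r_times must be one-dimensional")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("r_times must be strictly increasing")
        ann = tuple(self.annotations) if self.annotations else tuple([NORMAL] * times.size)
        if len(ann) != times.size:
            raise ValueError("annotations must match r_times length")
        object.__setattr__(self, "annotations", ann)

    @property
    def n_beats(self) -> int:
        return int(self.r_times.size)

    @property
    def rr(self) -> np.ndarray:
        """Successive R-R intervals in milliseconds (length ``n_beats - 1``)."""
        return np.diff(self.r_times) * 1000.0

    @property
    def span(self) -> tuple[float, float]:
        if self.n_beats == 0:
            return (0.0, 0.0)
        return (float(self.r_times[0]), float(self.r_times[-1]))


# --------------------------------------------------------------------------
# Session protocol
# --------------------------------------------------------------------------

BASELINE = "baseline"
STIMULUS = "stimulus"
REST = "rest"

BASELINE_DURATION = 60.0
STIMULUS_DURATION = 55.0
REST_DURATION = 55.0


@dataclass(frozen=True)
class ProtocolEvent:
    label: str                 # baseline | stimulus | rest
    condition: str | None      # acquaintance | stranger | None
    onset: float               # seconds
    duration: float            # seconds

    def __post_init__(self):
        if self.label not in (BASELINE, STIMULUS, REST):
            raise ValueError(f"unknown event label {self.label!r}")
        if (self.condition is not None) != (self.label == STIMULUS):
            raise ValueError("condition must be set iff the event is a stimulus")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.duration <= 0:
            raise ValueError("event duration must be positive")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @property
    def window(self) -> tuple[float, float]:
        return (self.onset, self.end)


@dataclass(frozen=True)
class SessionProtocol:
    """Ordered, contiguous timeline of baseline / stimulus / rest events.

    Invariants enforced at construction:

    * events are contiguous and non-overlapping, onsets strictly increasing;
    * exactly one 60-s baseline at onset 0;
    * every stimulus lasts 55 s and is immediately followed by a 55-s rest.
    """

    events: tuple[ProtocolEvent, ...]

    def __post_init__(self):
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        if not events:
            raise ValueError("protocol must contain at least one event")
        if events[0].label != BASELINE or events[0].onset != 0.0:
            raise ValueError("protocol must start with the baseline at onset 0")
        baselines = [e for e in events if e.label == BASELINE]
        if len(baselines) != 1 or baselines[0].duration != BASELINE_DURATION:
            raise ValueError("exactly one 60-s baseline event is required")
        for prev, nxt in zip(events, events[1:]):
            if not np.isclose(nxt.onset, prev.end):
                raise ValueError("events must be contiguous and non-overlapping")
        for i, e in enumerate(events):
            if e.label == STIMULUS:
                if e.duration != STIMULUS_DURATION:
                    raise ValueError("stimulus events must last 55 s")
                if i + 1 >= len(events) or events[i + 1].label != REST \
                        or events[i + 1].duration != REST_DURATION:
                    raise ValueError("every stimulus must be followed by a 55-s rest")

    def __iter__(self) -> Iterator[ProtocolEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def span(self) -> float:
        """Total session duration in seconds."""
        return self.events[-1].end

    @property
    def stimulus_events(self) -> tuple[ProtocolEvent, ...]:
        return tuple(e for e in self.events if e.label == STIMULUS)

    def condition_at(self, t: np.ndarray) -> np.ndarray:
        """Vectorized map time -> condition index (-1 none, else CONDITIONS index)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, -1, dtype=int)
        for e in self.stimulus_events:
            mask = (t >= e.onset) & (t < e.end)
            out[mask] = CONDITIONS.index(e.condition)
        return out

    def preceding_rest(self, stimulus_index: int) -> ProtocolEvent:
        """The rest (or baseline, for the first stimulus) immediately before
        the given stimulus event, in protocol order."""
        e = self.events[stimulus_index]
        if e.label != STIMULUS:
            raise ValueError("index does not refer to a stimulus event")
        prev = self.events[stimulus_index - 1]
        if prev.label not in (REST, BASELINE):
            raise ValueError("no resting period precedes this stimulus")
        return prev
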