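"""Seeded synthetic cohorts emulating the affective-video session design.

The generator produces, bottom-up:

1. a session timeline (60-s baseline, randomized 55-s videos of an
   acquaintance or a stranger, each followed by a 55-s rest),
2. beat sequences from an integrate-and-fire realization of a modulated
   instantaneous heart period with condition-dependent mean shifts,
3. ECG waveforms (template P-QRS-T pulses plus baseline wander, mains
   interference and broadband noise), and
4. injected ectopic beats with ground-truth annotations.

This is deliberately *not* a physiological simulator: its purpose is to give
every analysis stage a seeded ground-truth test surface with controllable
group- and condition-level effects.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import (
    BASELINE, BASELINE_DURATION, CONDITIONS, ECTOPIC, GROUPS, NORMAL, REST,
    REST_DURATION, STIMULUS, STIMULUS_DURATION, BeatSeries, ECGRecord,
    ProtocolEvent, SessionProtocol,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HeartPeriodModel", "NoiseSpec", "CohortSpec", "SubjectRecord",
    "generate_protocol", "generate_beats", "synthesize_ecg",
    "inject_ectopics", "generate_cohort",
]


# --------------------------------------------------------------------------
# Protocol
# --------------------------------------------------------------------------

def generate_protocol(seed: int, n_stimuli: int = 12,
                      sam_break: bool = False) -> SessionProtocol:
    """Build a session timeline with a seeded, balanced stimulus order.

    Parameters
    ----------
    seed : int
        Seed for the uniform shuffle of the condition sequence.
    n_stimuli : int
        Number of video presentations; must be even and positive so the two
        conditions are balanced (half acquaintance, half stranger).
    sam_break : bool
        If True, emulate the healthy-subject timeline in which each video is
        followed by a 55-s self-report period before the rest; it is emitted
        as an extra rest-labelled event (its content is out of scope here).
    """
    if n_stimuli < 2 or n_stimuli % 2 != 0:
        raise ValueError(
            f"n_stimuli must be a positive even integer (got {n_stimuli}): "
            "the design presents equally many acquaintance and stranger videos"
        )
    rng = np.random.default_rng(seed)
    conditions = [CONDITIONS[0]] * (n_stimuli // 2) + [CONDITIONS[1]] * (n_stimuli // 2)
    order = rng.permutation(n_stimuli)
    conditions = [conditions[i] for i in order]

    events = [ProtocolEvent(BASELINE, None, 0.0, BASELINE_DURATION)]
    t = BASELINE_DURATION
    for cond in conditions:
        events.append(ProtocolEvent(STIMULUS, cond, t, STIMULUS_DURATION))
        t += STIMULUS_DURATION
        if sam_break:
            events.append(ProtocolEvent(REST, None, t, REST_DURATION))
            t += REST_DURATION
        events.append(ProtocolEvent(REST, None, t, REST_DURATION))
        t += REST_DURATION
    return SessionProtocol(tuple(events))


# --------------------------------------------------------------------------
# Beat sequences
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HeartPeriodModel:
    """Instantaneous heart period m(t) in milliseconds.

    ``m(t) = m0 + A_LF sin(2π f_LF t) + A_HF sin(2π f_HF t) + delta(condition
    active at t) + noise``, with the LF/HF frequencies constrained to the
    conventional autonomic bands (LF 0.04-0.15 Hz, HF 0.15-0.4 Hz).  ``sigma``
    is the SD of per-beat Gaussian period noise (ms); ``delta`` maps each
    stimulus condition to an additive period shift active only during that
    condition's video windows.
    """

    m0: float = 850.0
    a_lf: float = 20.0
    f_lf: float = 0.1
    a_hf: float = 25.0
    f_hf: float = 0.25
    sigma: float = 10.0
    delta: dict = field(default_factory=lambda: {"acquaintance": 25.0, "stranger": 0.0})

    def __post_init__(self):
        if self.m0 <= 0:
            raise ValueError("baseline heart period m0 must be positive")
        if min(self.a_lf, self.a_hf, self.sigma) < 0:
            raise ValueError("amplitudes and sigma must be non-negative")
        if not (0.04 <= self.f_lf < 0.15 <= self.f_hf <= 0.4):
            raise ValueError("require 0.04 <= f_LF < 0.15 <= f_HF <= 0.4 Hz")
        for cond in self.delta:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} in delta")

    def scaled(self, effect_scale: float) -> "HeartPeriodModel":
        """Copy of the model with every condition shift multiplied by ``effect_scale``."""
        if effect_scale < 0:
            raise ValueError("effect scale must be non-negative")
        return replace(self, delta={c: v * effect_scale for c, v in self.delta.items()})

    def mean_period(self, t: np.ndarray, protocol: SessionProtocol) -> np.ndarray:
        """Deterministic part of m(t) in ms, vectorized over times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        m = self.m0 + self.a_lf * np.sin(2 * np.pi * self.f_lf * t) \
            + self.a_hf * np.sin(2 * np.pi * self.f_hf * t)
        cond_idx = protocol.condition_at(t)
        for i, cond in enumerate(CONDITIONS):
            shift = self.delta.get(cond, 0.0)
            if shift:
                m = np.where(cond_idx == i, m + shift, m)
        return m


def generate_beats(protocol: SessionProtocol, model: HeartPeriodModel,
                   seed: int, dt: float = 0.01) -> BeatSeries:
    """Integrate-and-fire beat times over the instantaneous rate 1/m(t).

    The deterministic rate 1000/m(t) (beats/s) is integrated on a fine grid;
    a beat fires at every unit crossing of the cumulative integral.  Per-beat
    Gaussian period noise (SD ``model.sigma`` ms) is then added to the
    resulting intervals and beat times are rebuilt cumulatively; noise draws
    are truncated so every interval stays positive.
    """
    tgrid = np.arange(0.0, protocol.span + dt, dt)
    m = model.mean_period(tgrid, protocol)
    if np.any(m <= 0):
        raise ValueError("instantaneous heart period m(t) must stay positive")
    rate = 1000.0 / m  # beats per second
    cum = cumulative_trapezoid(rate, tgrid, initial=0.0)
    n_beats = int(np.floor(cum[-1]))
    beat_times = np.interp(np.arange(n_beats + 1, dtype=float), cum, tgrid)

    if model.sigma > 0:
        rng = np.random.default_rng(seed)
        rr = np.diff(beat_times)
        noise = rng.normal(0.0, model.sigma / 1000.0, size=rr.size)
        # keep intervals physiologically positive under extreme draws
        rr = np.maximum(rr + noise, 0.2)
        beat_times = beat_times[0] + np.concatenate(([0.0], np.cumsum(rr)))
    return BeatSeries(beat_times)


# --------------------------------------------------------------------------
# ECG waveform synthesis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Additive contamination of the synthetic ECG (amplitudes in mV)."""

    wander_amp: float = 0.1     # baseline wander (respiration-like)
    wander_freq: float = 0.25   # Hz
    mains_amp: float = 0.05     # power-line interference
    mains_freq: float = 50.0    # Hz
    white_sd: float = 0.05      # broadband noise SD

    def __post_init__(self):
        if min(self.wander_amp, self.mains_amp, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be non-negative")

    @classmethod
    def clean(cls) -> "NoiseSpec":
        return cls(wander_amp=0.0, mains_amp=0.0, white_sd=0.0)


def _beat_template(fs: float) -> tuple[np.ndarray, int]:
    """P-QRS-T shaped pulse as a sum of Gaussians; returns (template, r_index).

    The R deflection (1 mV) dominates so the sample argmax of a clean record
    coincides with the annotated beat time.
    """
    t = np.arange(-0.25, 0.40, 1.0 / fs)
    waves = [  # (amplitude mV, center s, width s)
        (0.12, -0.18, 0.025),   # P
        (-0.10, -0.030, 0.010), # Q
        (1.00, 0.0, 0.012),     # R
        (-0.15, 0.030, 0.012),  # S
        (0.30, 0.22, 0.050),    # T
    ]
    tpl = np.zeros_like(t)
    for amp, mu, sd in waves:
        tpl += amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    r_index = int(np.argmin(np.abs(t)))
    return tpl, r_index


def synthesize_ecg(beats: BeatSeries, fs: float = 256.0,
                   noise: NoiseSpec | None = None, seed: int = 0) -> ECGRecord:
    """Place a template beat at each R time and add the configured noise.

    The record covers the last beat plus one second.  ``fs`` below 128 Hz is
    rejected: the 12-ms QRS template is not representable there.
    """
    if fs < 128.0:
        raise ValueError(f"fs={fs} Hz too low to represent the QRS template "
                         "(>= 128 Hz required)")
    if beats.n_beats == 0:
        raise ValueError("cannot synthesize ECG from an empty beat series")
    noise = noise or NoiseSpec()
    n = int(np.ceil((beats.r_times[-1] + 1.0) * fs))
    sig = np.zeros(n)
    tpl, r_index = _beat_template(fs)
    for bt in beats.r_times:
        i0 = int(round(bt * fs)) - r_index
        a, b = max(i0, 0), min(i0 + tpl.size, n)
        if a < b:
            sig[a:b] += tpl[a - i0:b - i0]

    t = np.arange(n) / fs
    if noise.wander_amp:
        sig = sig + noise.wander_amp * np.sin(2 * np.pi * noise.wander_freq * t)
    if noise.mains_amp:
        sig = sig + noise.mains_amp * np.sin(2 * np.pi * noise.mains_freq * t)
    if noise.white_sd:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise.white_sd, size=n)
    return ECGRecord(sig, fs)


# --------------------------------------------------------------------------
# Ectopic injection
# --------------------------------------------------------------------------

def inject_ectopics(beats: BeatSeries, fraction: float, seed: int = 0) -> BeatSeries:
    """Displace a seeded selection of beats early, with a compensatory pause.

    ``floor(fraction * n)`` non-adjacent interior beats are moved to 0.6x the
    preceding interval; the following beat time is untouched, so one ectopic
    turns a regular (RR, RR) pair into approximately (0.6 RR, 1.4 RR) and the
    total beat count is preserved.  Displaced beats carry the ground-truth
    ``ectopic`` annotation.
    """
    if not 0 <= fraction < 1:
        raise ValueError("ectopic fraction must lie in [0, 1)")
    n = beats.n_beats
    k = int(np.floor(fraction * n))
    if k == 0:
        return beats
    rng = np.random.default_rng(seed)
    candidates = rng.permutation(np.arange(1, n - 1))
    chosen: list[int] = []
    taken = np.zeros(n, dtype=bool)
    for c in candidates:
        if taken[c - 1] or taken[c] or taken[c + 1]:
            continue
        chosen.append(int(c))
        taken[c] = True
        if len(chosen) == k:
            break
    if len(chosen) < k:
        raise ValueError(
            f"cannot place {k} non-adjacent ectopics among {n} beats")
    times = beats.r_times.copy()
    ann = list(beats.annotations)
    for c in chosen:
        times[c] = times[c - 1] + 0.6 * (times[c] - times[c - 1])
        ann[c] = ECTOPIC
    return BeatSeries(times, tuple(ann))


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Specification of a seeded synthetic cohort.

    ``group_effect_scale`` multiplies the model's condition shifts per group;
    the default gives healthy controls the full effect and both patient
    groups none, the pattern against which the analysis chain is validated.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"HC": 17, "MCS": 5, "UWS": 6})
    group_effect_scale: dict = field(
        default_factory=lambda: {"HC": 1.0, "MCS": 0.0, "UWS": 0.0})
    model: HeartPeriodModel = field(default_factory=HeartPeriodModel)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_stimuli: int = 12
    sam_break: bool = False
    with_ecg: bool = False
    ecg_fs: float = 256.0
    ectopic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for g, c in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if c < 0:
                raise ValueError("group counts must be non-negative")
        for g, s in self.group_effect_scale.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if s < 0:
                raise ValueError("effect multipliers must be non-negative")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    protocol: SessionProtocol
    beats: BeatSeries
    ecg: ECGRecord | None = None
    truth_beats: BeatSeries | None = None  # pre-ectopic ground truth


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate one :class:`SubjectRecord` per subject, deterministically.

    Per-subject seeds are spawned from the master seed, so the same spec
    always yields byte-identical cohorts, and each subject's realization is
    independent of the others' counts only through ordering.
    """
    root = np.random.SeedSequence(spec.seed)
    subjects: list[SubjectRecord] = []
    total = sum(spec.n_per_group.get(g, 0) for g in GROUPS)
    children = root.spawn(total)
    idx = 0
    for group in GROUPS:
        scale = spec.group_effect_scale.get(group, 1.0)
        model = spec.model.scaled(scale)
        for i in range(spec.n_per_group.get(group, 0)):
            sub_seeds = children[idx].generate_state(4) % (2 ** 31)
            idx += 1
            protocol = generate_protocol(int(sub_seeds[0]), spec.n_stimuli,
                                         sam_break=spec.sam_break)
            beats = generate_beats(protocol, model, int(sub_seeds[1]))
            truth = None
            if spec.ectopic_fraction > 0:
                truth = beats
                beats = inject_ectopics(beats, spec.ectopic_fraction,
                                        int(sub_seeds[2]))
            ecg = None
            if spec.with_ecg:
                ecg = synthesize_ecg(beats, spec.ecg_fs, spec.noise,
                                     int(sub_seeds[3]))
            subjects.append(SubjectRecord(
                subject_id=f"{group}{i + 1:02d}", group=group,
                protocol=protocol, beats=beats, ecg=ecg, truth_beats=truth))
    logger.info("generated cohort: %s subjects (%s)", len(subjects),
                {g: spec.n_per_group.get(g, 0) for g in GROUPS})
    return subjects
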