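"""Protocol-aligned feature extraction and rest-referenced normalization.

For every subject, each protocol event (baseline, stimulus, rest) yields one
feature window.  Each stimulation window is then normalized as

    value = (feature(stimulus) - feature(preceding rest)) / MAD_subject

where the preceding rest is the rest — or, for the first video, the baseline
— immediately before the stimulus in protocol order, and MAD_subject is the
raw median absolute deviation of that feature across *all* of the subject's
windows (stimuli, rests and baseline).  Using all windows keeps condition
information out of the scale; the raw (unscaled) MAD is used because this is
a normalization denominator, not an SD estimate.  Both choices are
configurable.

Missing data are excluded at the finest granularity (window-feature) with a
machine-readable reason, never imputed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FEATURE_NAMES, STIMULUS, BeatSeries, SessionProtocol
from .features import MAD_CONSISTENCY, FeatureVector, extract_features
from .simulate import SubjectRecord

logger = logging.getLogger(__name__)

__all__ = ["segment_windows", "subject_mad", "normalize", "run_cohort",
           "CohortTables"]

MAD_FLOOR = 1e-9
LONG_COLUMNS = ["subject_id", "group", "window_id", "condition", "feature", "value"]


def segment_windows(beats: BeatSeries, protocol: SessionProtocol,
                    mad_consistency: bool = True) -> list[FeatureVector]:
    """One :class:`FeatureVector` per protocol event, in protocol order.

    Windows the beat series does not cover come back as explicit invalid
    markers (and a warning is logged), so downstream stages see missingness
    rather than silence.
    """
    out: list[FeatureVector] = []
    last_beat = beats.r_times[-1] if beats.n_beats else 0.0
    for i, event in enumerate(protocol):
        wid = f"w{i:02d}:{event.label}"
        fv = extract_features(beats, event.window, window_id=wid,
                              mad_consistency=mad_consistency)
        if not fv.valid and event.onset < last_beat:
            logger.warning("window %s has too few beats; marked missing", wid)
        elif not fv.valid:
            logger.warning("window %s beyond beat coverage; marked missing", wid)
        out.append(fv)
    return out


def subject_mad(values: np.ndarray, consistency: bool = False
                ) -> tuple[float, bool] | None:
    """Per-subject scale of one feature across its non-missing windows.

    Returns ``(scale, degenerate)`` or None when fewer than 3 windows are
    available (the subject is then excluded for that feature).  A zero MAD
    falls back to a small positive floor with the degenerate flag set.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        return None
    mad = float(np.median(np.abs(values - np.median(values))))
    if consistency:
        mad *= MAD_CONSISTENCY
    if mad == 0.0:
        return MAD_FLOOR, True
    return mad, False


def normalize(stim_fv: FeatureVector, rest_fv: FeatureVector,
              scale: dict[str, float]) -> dict[str, float]:
    """(stimulus - preceding rest) / subject MAD, per feature.

    Features whose scale is unavailable, or that are NaN in either window,
    are omitted from the result (handled as missing upstream).
    """
    if not (stim_fv.valid and rest_fv.valid):
        raise ValueError("both windows must be valid")
    out: dict[str, float] = {}
    stim, rest = stim_fv.as_dict(), rest_fv.as_dict()
    for name in FEATURE_NAMES:
        s = scale.get(name)
        if s is None or not (np.isfinite(stim[name]) and np.isfinite(rest[name])):
            continue
        out[name] = (stim[name] - rest[name]) / s
    return out


@dataclass
class CohortTables:
    """Long-form normalized values, per-condition subject means, exclusions."""

    long: pd.DataFrame
    condition_means: pd.DataFrame
    exclusions: list[dict] = field(default_factory=list)


def run_cohort(subjects: list[SubjectRecord], mad_consistency_scale: bool = False,
               feature_mad_consistency: bool = True) -> CohortTables:
    """Segment, normalize and summarize every subject of a cohort.

    Returns the long table of normalized window-level values (one row per
    subject x stimulus window x feature) together with the per subject x
    condition x feature means across that condition's windows — the "then
    averaged" summary consumed by the statistical layer — and a structured
    exclusion log.
    """
    rows: list[tuple] = []
    exclusions: list[dict] = []
    for subj in subjects:
        fvs = segment_windows(subj.beats, subj.protocol,
                              mad_consistency=feature_mad_consistency)
        # per-feature scale over ALL of the subject's windows
        scale: dict[str, float] = {}
        for name in FEATURE_NAMES:
            vals = np.array([getattr(fv, name) for fv in fvs if fv.valid])
            res = subject_mad(vals, consistency=mad_consistency_scale)
            if res is None:
                exclusions.append({"subject_id": subj.subject_id,
                                   "feature": name, "reason": "too_few_windows"})
                continue
            mad, degenerate = res
            if degenerate:
                exclusions.append({"subject_id": subj.subject_id,
                                   "feature": name, "reason": "degenerate_mad"})
            scale[name] = mad

        for i, event in enumerate(subj.protocol):
            if event.label != STIMULUS:
                continue
            stim_fv = fvs[i]
            rest_fv = fvs[i - 1]
            if not stim_fv.valid or not rest_fv.valid:
                exclusions.append({
                    "subject_id": subj.subject_id, "window_id": f"w{i:02d}",
                    "reason": "invalid_window" if not stim_fv.valid
                    else "invalid_preceding_rest"})
                continue
            normed = normalize(stim_fv, rest_fv, scale)
            for name, value in normed.items():
                rows.append((subj.subject_id, subj.group, f"w{i:02d}",
                             event.condition, name, value))

    long = pd.DataFrame(rows, columns=LONG_COLUMNS)
    if long.empty:
        cond_means = pd.DataFrame(
            columns=["subject_id", "group", "condition", "feature", "value"])
    else:
        cond_means = (long.groupby(
            ["subject_id", "group", "condition", "feature"], observed=True,
            sort=False)["value"].mean().reset_index())
    return CohortTables(long=long, condition_means=cond_means,
                        exclusions=exclusions)
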