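"""Readers, writers and run configuration.

CSV is the canonical inter-stage format (inspectable, diff-able): ECG as
``time_s,mV`` with the sampling rate in a ``# fs=...`` header comment, beats
as ``time_s,annotation``, feature and results tables as tidy CSV.  Protocols
serialize to YAML (or JSON) with the event schema of
:class:`~hrvaffect.core.SessionProtocol`.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BeatSeries, ECGRecord, ProtocolEvent, SessionProtocol

__all__ = [
    "read_ecg_csv", "write_ecg_csv", "read_beats_csv", "write_beats_csv",
    "read_protocol", "write_protocol", "load_config", "default_config",
    "config_hash",
]


# --------------------------------------------------------------------------
# Signals and beats
# --------------------------------------------------------------------------

def write_ecg_csv(record: ECGRecord, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={record.fs}\n")
        fh.write("time_s,mV\n")
        times = record.times
        for t, v in zip(times, record.samples):
            fh.write(f"{t:.6f},{v:.6f}\n")


def read_ecg_csv(path: str | Path) -> ECGRecord:
    path = Path(path)
    fs = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# fs="):
            fs = float(first.strip().split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if not {"time_s", "mV"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,mV")
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        if t.size < 2:
            raise ValueError(f"{path}: cannot infer sampling rate")
        fs = 1.0 / float(np.median(np.diff(t)))
    return ECGRecord(df["mV"].to_numpy(dtype=float), fs=fs,
                     t0=float(t[0]) if t.size else 0.0)


def write_beats_csv(beats: BeatSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": beats.r_times,
                  "annotation": list(beats.annotations)}
                 ).to_csv(path, index=False, float_format="%.6f")


def read_beats_csv(path: str | Path) -> BeatSeries:
    df = pd.read_csv(path)
    if not {"time_s", "annotation"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,annotation")
    return BeatSeries(df["time_s"].to_numpy(dtype=float),
                      tuple(df["annotation"].astype(str)))


# --------------------------------------------------------------------------
# Protocols
# --------------------------------------------------------------------------

def _protocol_to_obj(protocol: SessionProtocol) -> dict:
    return {"events": [
        {"label": e.label, "condition": e.condition,
         "onset": float(e.onset), "duration": float(e.duration)}
        for e in protocol]}


def write_protocol(protocol: SessionProtocol, path: str | Path) -> None:
    path = Path(path)
    obj = _protocol_to_obj(protocol)
    with path.open("w") as fh:
        if path.suffix == ".json":
            json.dump(obj, fh, indent=2)
        else:
            yaml.safe_dump(obj, fh, sort_keys=False)


def read_protocol(path: str | Path) -> SessionProtocol:
    path = Path(path)
    with path.open() as fh:
        obj = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    events = tuple(ProtocolEvent(e["label"], e.get("condition"),
                                 float(e["onset"]), float(e["duration"]))
                   for e in obj["events"])
    return SessionProtocol(events)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

def default_config() -> dict:
    """Every tunable of the pipeline with its default, as a nested dict."""
    return {
        "seed": 0,
        "simulate": {
            "n_per_group": {"HC": 17, "MCS": 5, "UWS": 6},
            "group_effect_scale": {"HC": 1.0, "MCS": 0.0, "UWS": 0.0},
            "model": {"m0": 850.0, "a_lf": 20.0, "f_lf": 0.1,
                      "a_hf": 25.0, "f_hf": 0.25, "sigma": 10.0,
                      "delta": {"acquaintance": 25.0, "stranger": 0.0}},
            "noise": {"wander_amp": 0.1, "wander_freq": 0.25,
                      "mains_amp": 0.05, "mains_freq": 50.0, "white_sd": 0.05},
            "n_stimuli": 12,
            "sam_break": False,
            "with_ecg": False,
            "ectopic_fraction": 0.0,
        },
        "resample": {"target_fs": 256.0},
        "highpass": {"order": 5, "fc": 0.5},
        "notch": {"f0": 50.0, "q": 30.0},
        "ectopic": {"max_fraction": 0.20, "tol": 0.2, "k": 5},
        "features": {"mad_consistency": True},
        "pipeline": {"mad_consistency_scale": False},
        "stats": {"alpha": 0.05, "family_size": 12, "unit": "window"},
        "log_level": "INFO",
    }


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with the YAML file at ``path`` (if given)."""
    cfg = default_config()
    if path is not None:
        with Path(path).open() as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg = _deep_merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash of a config, for run manifests."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
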