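"""On-disk formats: BIDS-style events TSV, raw binary + JSON sidecar, epochs.

The continuous container is a flat float32 little-endian array
(channels x samples, channel-major) next to a ``.json`` sidecar recording
the sampling rate, channel names, shape and units (microvolts).  Events
tables follow BIDS conventions: onsets and durations in seconds, one row
per trial, extra task columns preserved.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .synth import SubjectData, SubjectSpec

__all__ = [
    "save_events_tsv",
    "load_events_tsv",
    "save_raw",
    "load_raw",
    "save_subject",
    "load_subject",
    "save_epochs",
    "load_epochs",
]


def save_events_tsv(path: str | Path, trials: pd.DataFrame, sensory_ms: float = 1000.0) -> Path:
    """Write the trial schedule as a BIDS-style events file."""
    path = Path(path)
    ev = pd.DataFrame(
        {
            "onset": trials["onset_ms"] / 1000.0,
            "duration": sensory_ms / 1000.0,
            "trial_type": trials["category"],
            "stimulus_id": trials["stimulus_id"],
            "block": trials["block"],
            "probe_match": trials["probe_match"].astype(int),
            "response": trials["response"].fillna("n/a"),
            "correct": trials["correct"].astype("boolean").map(
                {True: 1, False: 0}, na_action="ignore"
            ).fillna("n/a"),
        }
    )
    ev.to_csv(path, sep="\t", index=False)
    return path


def load_events_tsv(path: str | Path) -> pd.DataFrame:
    """Read an events TSV back into the internal trial-table layout."""
    ev = pd.read_csv(path, sep="\t", na_values=["n/a"])
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(len(ev)),
            "block": ev["block"].astype(int),
            "category": ev["trial_type"].astype(object),
            "stimulus_id": ev["stimulus_id"].astype(int),
            "probe_match": ev["probe_match"].astype(bool),
            "onset_ms": ev["onset"] * 1000.0,
            "response": ev["response"].astype("string"),
            "correct": ev["correct"].map({1: True, 0: False, 1.0: True, 0.0: False}).astype(
                "boolean"
            ),
        }
    )
    return trials


def save_raw(
    prefix: str | Path,
    data: np.ndarray,
    fs_hz: float,
    channel_names: list[str] | None = None,
) -> tuple[Path, Path]:
    """Write float32 binary + JSON sidecar; returns (bin_path, json_path)."""
    prefix = Path(prefix)
    bin_path = prefix.with_suffix(".bin")
    json_path = prefix.with_suffix(".json")
    arr = np.ascontiguousarray(data, dtype="<f4")
    arr.tofile(bin_path)
    sidecar = {
        "fs_hz": fs_hz,
        "n_channels": int(arr.shape[0]),
        "n_samples": int(arr.shape[1]),
        "dtype": "<f4",
        "order": "channel-major",
        "units": "uV",
        "channel_names": channel_names or [f"ch{i:02d}" for i in range(arr.shape[0])],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return bin_path, json_path


def load_raw(prefix: str | Path) -> tuple[np.ndarray, float, list[str]]:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".bin"), dtype=sidecar["dtype"]).reshape(
        sidecar["n_channels"], sidecar["n_samples"]
    )
    return data, float(sidecar["fs_hz"]), sidecar["channel_names"]


def save_subject(out_dir: str | Path, sub: SubjectData) -> dict:
    """Persist one synthetic subject (raw container + events + subject JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = sub.subject.subject_id
    paths = {}
    b, j = save_raw(out_dir / f"{sid}_eeg", sub.data, sub.fs_hz, sub.channel_names)
    paths["raw_bin"], paths["raw_json"] = str(b), str(j)
    paths["events"] = str(save_events_tsv(out_dir / f"{sid}_events.tsv", sub.trials))
    meta = {
        "subject_id": sid,
        "age_months": sub.subject.age_months,
        "snr_multiplier": sub.subject.snr_multiplier,
        "behavioral_accuracy": sub.subject.behavioral_accuracy,
    }
    meta_path = out_dir / f"{sid}_subject.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    paths["subject"] = str(meta_path)
    return paths


def load_subject(out_dir: str | Path, subject_id: str) -> SubjectData:
    out_dir = Path(out_dir)
    data, fs, names = load_raw(out_dir / f"{subject_id}_eeg")
    trials = load_events_tsv(out_dir / f"{subject_id}_events.tsv")
    meta = json.loads((out_dir / f"{subject_id}_subject.json").read_text())
    spec = SubjectSpec(
        subject_id=meta["subject_id"],
        age_months=meta["age_months"],
        snr_multiplier=meta["snr_multiplier"],
        behavioral_accuracy=meta["behavioral_accuracy"],
    )
    return SubjectData(subject=spec, data=data, fs_hz=fs, trials=trials, channel_names=names)


def save_epochs(prefix: str | Path, ep: EpochSet) -> tuple[Path, Path]:
    """Epochs container: float32 binary (trials x channels x samples) + sidecar."""
    prefix = Path(prefix)
    bin_path = prefix.with_suffix(".epo.bin")
    json_path = prefix.with_suffix(".epo.json")
    arr = np.ascontiguousarray(ep.data, dtype="<f4")
    arr.tofile(bin_path)
    sidecar = {
        "shape": list(arr.shape),
        "dtype": "<f4",
        "fs_hz": ep.fs_hz,
        "times_ms": [float(ep.times_ms[0]), float(ep.times_ms[-1])],
        "units": "uV",
        "labels": [str(c) for c in ep.labels],
        "trial_meta": ep.trial_meta.astype(object).where(ep.trial_meta.notna(), None)
        .to_dict(orient="list"),
        "subject": None
        if ep.subject_meta is None
        else {
            "subject_id": ep.subject_meta.subject_id,
            "age_months": ep.subject_meta.age_months,
            "snr_multiplier": ep.subject_meta.snr_multiplier,
            "behavioral_accuracy": ep.subject_meta.behavioral_accuracy,
        },
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return bin_path, json_path


def load_epochs(prefix: str | Path) -> EpochSet:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".epo.json").read_text())
    shape = tuple(sidecar["shape"])
    data = np.fromfile(prefix.with_suffix(".epo.bin"), dtype=sidecar["dtype"]).reshape(shape)
    fs = float(sidecar["fs_hz"])
    t0 = sidecar["times_ms"][0]
    times = t0 + np.arange(shape[2]) * 1000.0 / fs
    meta = pd.DataFrame(sidecar["trial_meta"])
    subject = None
    if sidecar["subject"]:
        subject = SubjectSpec(**sidecar["subject"])
    return EpochSet(
        data=data,
        times_ms=times,
        fs_hz=fs,
        labels=np.array(sidecar["labels"], dtype=object),
        trial_meta=meta,
        subject_meta=subject,
    )
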