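"""Continuous-to-epochs preprocessing.

Implements the automatic part of a standard children's-EEG cleaning chain:
downsample, DC removal, zero-phase 1-40 Hz Butterworth bandpass
(12 dB/octave per pass, applied forward and backward), epoching on a
half-open [-300, 3000) ms window, +/-150 uV amplitude rejection, behavioral
scoring, and cohort-level exclusion rules (behavioral accuracy at or below
the 50% guessing level, or 200 or fewer retained trials).

Interactive cleaning steps (ICA-based blink removal, visual inspection,
spline interpolation of bad channels) are intentionally not part of this
module; users with real recordings should supply data that already went
through such steps.  The exclusion report flags that only the automatic
amplitude criterion was applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ConfigurationError, PipelineError
from .synth import SubjectData, SubjectSpec

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocConfig",
    "EpochSet",
    "bandpass_resample",
    "epoch",
    "reject_artifacts",
    "score_behavior",
    "apply_exclusions",
    "preprocess_subject",
]


@dataclass(frozen=True)
class PreprocConfig:
    """Filtering, epoching, rejection and exclusion parameters."""

    fs_target_hz: float = 500.0
    band_hz: tuple[float, float] = (1.0, 40.0)
    epoch_window_ms: tuple[float, float] = (-300.0, 3000.0)
    reject_uv: float = 150.0
    min_trials: int = 200
    behav_chance: float = 0.50

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ConfigurationError("band_hz must satisfy 0 < low < high")
        if hi >= self.fs_target_hz / 2:
            raise ConfigurationError("band high edge must be below fs_target/2")
        w0, w1 = self.epoch_window_ms
        if not w0 <= 0 < w1:
            raise ConfigurationError("epoch window must contain time 0")
        if self.reject_uv <= 0:
            raise ConfigurationError("reject_uv must be > 0")


@dataclass
class EpochSet:
    """Epoched trials for one subject.

    ``data`` is trials x channels x samples in microvolts; ``times_ms``
    spans the half-open epoch window at ``fs_hz``; ``labels`` holds the
    per-trial category; ``trial_meta`` is the retained subset of the trial
    schedule, row-aligned with ``data``.
    """

    data: np.ndarray
    times_ms: np.ndarray
    fs_hz: float
    labels: np.ndarray
    trial_meta: pd.DataFrame
    subject_meta: SubjectSpec | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != self.data.shape[0] or len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("labels/trial_meta must be row-aligned with data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Row-subset epochs, labels and metadata consistently."""
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            times_ms=self.times_ms,
            fs_hz=self.fs_hz,
            labels=self.labels[mask],
            trial_meta=self.trial_meta.iloc[np.flatnonzero(mask)
                                            if mask.dtype == bool else mask].reset_index(drop=True),
            subject_meta=self.subject_meta,
        )


def _bandpass_sos(band_hz: tuple[float, float], fs: float) -> np.ndarray:
    # order-2 Butterworth = 12 dB/octave per pass; filtfilt doubles the
    # effective order and cancels phase
    return signal.butter(2, band_hz, btype="bandpass", fs=fs, output="sos")


def bandpass_resample(
    data: np.ndarray, fs_in: float, cfg: PreprocConfig
) -> tuple[np.ndarray, float]:
    """Downsample to ``fs_target_hz``, remove DC, zero-phase bandpass.

    Returns ``(filtered, fs_target)``.  Upsampling is refused.
    """
    if cfg.fs_target_hz > fs_in:
        raise ConfigurationError(
            f"fs_target_hz={cfg.fs_target_hz} exceeds input rate {fs_in}; no upsampling"
        )
    x = np.asarray(data, dtype=np.float64)
    if cfg.fs_target_hz != fs_in:
        frac = Fraction(cfg.fs_target_hz / fs_in).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    sos = _bandpass_sos(cfg.band_hz, cfg.fs_target_hz)
    x = signal.sosfiltfilt(sos, x, axis=-1)
    return x.astype(np.float32), cfg.fs_target_hz


def epoch(
    data: np.ndarray,
    fs_hz: float,
    events: pd.DataFrame,
    cfg: PreprocConfig,
    subject_meta: SubjectSpec | None = None,
) -> EpochSet:
    """Cut one epoch per event on the half-open window ``epoch_window_ms``.

    Sample 0 of each epoch corresponds to the window start (default
    -300 ms).  Events whose window does not fit inside the recording are
    dropped with a warning.  No baseline correction is applied here:
    demeaning happens at classification time.
    """
    w0, w1 = cfg.epoch_window_ms
    n_samp = round((w1 - w0) * fs_hz / 1000.0)
    if n_samp < 1:
        raise ConfigurationError("epoch window is empty")
    onsets = np.round((events["onset_ms"].to_numpy() + w0) * fs_hz / 1000.0).astype(int)
    ok = (onsets >= 0) & (onsets + n_samp <= data.shape[-1])
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} event(s) fall outside the recording and were dropped",
            stacklevel=2,
        )
        logger.warning("epoch: dropped %d out-of-bounds event(s)", n_bad)
    kept = np.flatnonzero(ok)
    epochs = np.stack(
        [data[:, onsets[i] : onsets[i] + n_samp] for i in kept], axis=0
    ) if len(kept) else np.empty((0, data.shape[0], n_samp), dtype=data.dtype)
    meta = events.iloc[kept].reset_index(drop=True)
    times = w0 + np.arange(n_samp) * 1000.0 / fs_hz
    return EpochSet(
        data=epochs.astype(np.float32),
        times_ms=times,
        fs_hz=fs_hz,
        labels=meta["category"].to_numpy(dtype=object) if "category" in meta else
        np.array([None] * len(meta), dtype=object),
        trial_meta=meta,
        subject_meta=subject_meta,
    )


def reject_artifacts(ep: EpochSet, cfg: PreprocConfig) -> tuple[EpochSet, pd.DataFrame]:
    """Remove every trial exceeding +/-``reject_uv`` on any channel/sample.

    Returns the cleaned EpochSet and a rejection log listing, per removed
    trial, the offending channels.
    """
    bad_cs = np.abs(ep.data) > cfg.reject_uv  # trials x channels x samples
    bad_chan = bad_cs.any(axis=2)
    bad_trial = bad_chan.any(axis=1)
    rows = [
        {
            "trial_index": int(ep.trial_meta["trial_index"].iloc[i])
            if "trial_index" in ep.trial_meta
            else int(i),
            "row": int(i),
            "channels": ",".join(str(c) for c in np.flatnonzero(bad_chan[i])),
        }
        for i in np.flatnonzero(bad_trial)
    ]
    log = pd.DataFrame(rows, columns=["trial_index", "row", "channels"])
    logger.debug("reject_artifacts: removed %d/%d trials", len(log), ep.n_trials)
    return ep.select(~bad_trial), log


def score_behavior(trials: pd.DataFrame) -> float:
    """Proportion of correct responses over all trials.

    Missing responses count as incorrect, so the denominator is the full
    trial count.
    """
    if len(trials) == 0:
        raise PipelineError("cannot score behavior on an empty trial table")
    correct = trials["correct"].fillna(False).to_numpy(dtype=bool)
    return float(correct.mean())


def apply_exclusions(
    subjects: list[tuple[EpochSet, float]],
    cfg: PreprocConfig | None = None,
) -> tuple[list[EpochSet], pd.DataFrame]:
    """Apply cohort inclusion rules.

    A subject is excluded iff behavioral accuracy is at or below
    ``behav_chance`` (inclusive) or the retained trial count is not
    strictly greater than ``min_trials``.  Returns the retained EpochSets
    and a per-subject report.  Only the automatic amplitude criterion
    feeds the trial counts; no manual-inspection equivalent is applied,
    which the report notes.
    """
    cfg = cfg or PreprocConfig()
    rows, retained = [], []
    for ep, acc in subjects:
        n = ep.n_trials
        reasons = []
        if acc <= cfg.behav_chance:
            reasons.append(f"behavioral accuracy {acc:.3f} <= {cfg.behav_chance}")
        if n <= cfg.min_trials:
            reasons.append(f"retained trials {n} <= {cfg.min_trials}")
        excluded = bool(reasons)
        rows.append(
            {
                "subject_id": ep.subject_meta.subject_id if ep.subject_meta else "?",
                "n_trials_retained": n,
                "behavioral_accuracy": acc,
                "excluded": excluded,
                "reason": "; ".join(reasons),
                "criteria": "automatic amplitude rejection only (no manual inspection)",
            }
        )
        if not excluded:
            retained.append(ep)
    report = pd.DataFrame(rows)
    if not retained:
        raise PipelineError("all subjects excluded; group statistics undefined")
    return retained, report


def preprocess_subject(sub: SubjectData, cfg: PreprocConfig | None = None) -> tuple[EpochSet, pd.DataFrame, float]:
    """Convenience chain: filter/resample -> epoch -> reject -> score.

    Returns ``(clean_epochs, rejection_log, behavioral_accuracy)``.
    """
    cfg = cfg or PreprocConfig()
    filt, fs = bandpass_resample(sub.data, sub.fs_hz, cfg)
    ep = epoch(filt, fs, sub.trials, cfg, subject_meta=sub.subject)
    clean, log = reject_artifacts(ep, cfg)
    acc = score_behavior(sub.trials)
    return clean, log, acc
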