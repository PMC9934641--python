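"""Shared fixtures: reduced-scale sessions so the suite stays fast.

Decoding-level tests mostly build epochs directly from class-conditional
Gaussian features (via ``gaussian_epochs``) instead of running the full
forward synthesis, which keeps per-test cost in milliseconds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wmdecode.preprocess import EpochSet, PreprocConfig
from wmdecode.synth import CATEGORIES, SessionConfig, SignalModel, SubjectSpec


@pytest.fixture
def fast_cfg() -> SessionConfig:
    """Small session synthesized at a reduced rate."""
    return SessionConfig(n_trials_per_category=30, fs_raw_hz=250.0)


@pytest.fixture
def fast_pp() -> PreprocConfig:
    """Preprocessing matched to the reduced synthesis rate."""
    return PreprocConfig(fs_target_hz=125.0, min_trials=0)


@pytest.fixture
def quiet_model() -> SignalModel:
    return SignalModel(artifact_rate=0.0)


@pytest.fixture
def subject_spec() -> SubjectSpec:
    return SubjectSpec(subject_id="sub-001")


def make_epochset(
    data: np.ndarray, fs_hz: float = 100.0, labels=None, t0_ms: float = -300.0,
    blocks=None,
) -> EpochSet:
    """Wrap a trials x channels x samples array into an EpochSet."""
    n = data.shape[0]
    labels = np.asarray(
        labels if labels is not None else np.resize(np.array(CATEGORIES, object), n),
        dtype=object,
    )
    meta = pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "block": blocks if blocks is not None else 1 + (8 * np.arange(n)) // max(n, 1),
            "category": labels,
        }
    )
    times = t0_ms + np.arange(data.shape[2]) * 1000.0 / fs_hz
    return EpochSet(
        data=np.asarray(data, dtype=np.float32),
        times_ms=times,
        fs_hz=fs_hz,
        labels=labels,
        trial_meta=meta,
        subject_meta=SubjectSpec(subject_id="sub-mem"),
    )


def gaussian_epochs(
    rng: np.random.Generator,
    n_per_class: int = 45,
    n_channels: int = 16,
    separation: float = 1.0,
    n_samples: int = 33,
    fs_hz: float = 10.0,
    noise_sd: float = 1.0,
) -> EpochSet:
    """Epochs whose time-constant features are 3 Gaussian class clouds.

    The epoch spans [-300, 3000) ms at ``fs_hz`` so the default analysis
    windows apply; every sample holds the trial's feature vector, making
    window averages equal the features themselves.
    """
    means = rng.standard_normal((3, n_channels))
    means *= separation / np.linalg.norm(means, axis=1, keepdims=True)
    feats, labels = [], []
    for k, cat in enumerate(CATEGORIES):
        feats.append(means[k] + noise_sd * rng.standard_normal((n_per_class, n_channels)))
        labels += [cat] * n_per_class
    X = np.concatenate(feats)
    order = rng.permutation(len(X))
    X, labels = X[order], np.array(labels, object)[order]
    data = np.repeat(X[:, :, None], n_samples, axis=2)
    return make_epochset(data, fs_hz=fs_hz, labels=labels)
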