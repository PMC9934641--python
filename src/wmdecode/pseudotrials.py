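"""Pseudo-trial construction: window averaging, grouping, balancing, demeaning.

Single-trial EEG is too noisy for reliable category readout, so trials of
the same class are averaged in small groups ("pseudo-trials", group size 5
by default) before classification.  Class counts are then equalized by
stratified up-sampling and features are demeaned using training-partition
column means only, so no test-set information leaks into the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .preprocess import EpochSet

__all__ = [
    "PseudoTrialSet",
    "window_average",
    "make_pseudotrials",
    "stratify_upsample",
    "demean",
]


@dataclass
class PseudoTrialSet:
    """Averaged, class-labelled feature rows.

    ``provenance[i]`` lists the source-trial row indices averaged into
    pseudo-trial i.
    """

    features: np.ndarray  # pseudo-trials x features
    labels: np.ndarray
    group_size: int
    provenance: list[np.ndarray]


def window_average(ep: EpochSet, window_ms: tuple[float, float]) -> np.ndarray:
    """Mean voltage per trial and channel over the half-open window [start, end)."""
    lo, hi = window_ms
    if hi <= lo:
        raise ConfigurationError(f"empty window {window_ms}")
    mask = (ep.times_ms >= lo) & (ep.times_ms < hi)
    if not mask.any():
        raise ConfigurationError(f"window {window_ms} contains no samples")
    return ep.data[:, :, mask].mean(axis=2)


def make_pseudotrials(
    X: np.ndarray,
    y: np.ndarray,
    group_size: int = 5,
    rng: np.random.Generator | int | None = None,
) -> PseudoTrialSet:
    """Randomly partition each class into consecutive groups of ``group_size``
    and average within groups.

    Remainder trials (class count modulo group size) are dropped so every
    pseudo-trial has identical noise level.  ``X`` may have any feature
    shape beyond the first axis (channels, or channels x bins).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(X)
    y = np.asarray(y)
    feats, labels, prov = [], [], []
    for cls in _class_order(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < group_size:
            raise ConfigurationError(
                f"class {cls!r} has {len(idx)} trials, fewer than group_size={group_size}"
            )
        perm = rng.permutation(idx)
        n_groups = len(idx) // group_size
        for g in range(n_groups):
            members = perm[g * group_size : (g + 1) * group_size]
            feats.append(X[members].mean(axis=0))
            labels.append(cls)
            prov.append(members)
    return PseudoTrialSet(
        features=np.stack(feats),
        labels=np.array(labels, dtype=object),
        group_size=group_size,
        provenance=prov,
    )


def stratify_upsample(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate minority-class rows (uniformly, with replacement) until all
    class counts equal the majority count.

    Applied independently within training and test partitions by the
    caller; already-balanced input is returned unchanged.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(X)
    y = np.asarray(y)
    classes = _class_order(y)
    counts = {c: int((y == c).sum()) for c in classes}
    target = max(counts.values())
    extra_idx = []
    for c in classes:
        deficit = target - counts[c]
        if deficit > 0:
            pool = np.flatnonzero(y == c)
            extra_idx.append(rng.choice(pool, size=deficit, replace=True))
    if not extra_idx:
        return X, y
    extra = np.concatenate(extra_idx)
    return np.concatenate([X, X[extra]]), np.concatenate([y, y[extra]])


def demean(
    train_X: np.ndarray, test_X: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Subtract training-partition column means from both partitions.

    Returns ``(train', test', column_means)``; the test partition never
    contributes to the means (no leakage).
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    if train_X.shape[0] == 0:
        raise ConfigurationError("cannot demean an empty training partition")
    mu = train_X.mean(axis=0)
    test_out = None if test_X is None else np.asarray(test_X, dtype=np.float64) - mu
    return train_X - mu, test_out, mu


def _class_order(y: np.ndarray) -> list:
    """Stable, deterministic class ordering (sorted by string form)."""
    return sorted(set(y.tolist()), key=str)
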