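"""Per-subject decoding analyses.

Orchestrates the classification pipeline on epoched data:

* time-averaged window decoding (Baseline / Sensory / Delay),
* temporal generalization (train each time bin, test all bins),
* split-half analyses over early (blocks 1-4) and late (blocks 5-8)
  session halves, and early-to-late cross-decoding.

Every analysis repeats, over ``n_iterations`` seeded resamples, the same
leakage-safe per-iteration chain: trial-level stratified split (2/3 train,
1/3 test) -> pseudo-trial averaging within each partition -> stratified
up-sampling within each partition -> demeaning with training-derived
column means -> shrinkage-LDA fit and prediction.  Splitting happens at
the single-trial level so no source trial can contribute to averages on
both sides of the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lda
from .exceptions import ConfigurationError, PipelineError
from .preprocess import EpochSet
from .pseudotrials import make_pseudotrials, stratify_upsample, window_average

DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "Baseline": (-300.0, 0.0),
    "Sensory": (0.0, 1000.0),
    "Delay": (1000.0, 3000.0),
}

__all__ = [
    "CvScheme",
    "DecodingResult",
    "GenMatrix",
    "DEFAULT_WINDOWS",
    "decode_features",
    "decode_window",
    "decode_timeavg_all",
    "temporal_generalization",
    "split_half_decode",
    "cross_decode",
]


@dataclass(frozen=True)
class CvScheme:
    """Resampling scheme shared by all decoding analyses."""

    n_iterations: int = 100
    train_fraction: float = 2.0 / 3.0
    group_size: int = 5
    shrinkage: float | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.group_size < 1:
            raise ConfigurationError("group_size must be >= 1")


@dataclass
class DecodingResult:
    """Accuracy distribution and mean confusion for one analysis window."""

    window: str
    per_iteration_accuracy: np.ndarray
    mean_accuracy: float
    confusion: pd.DataFrame  # mean row-stochastic matrix
    n_trials_per_class: dict = field(default_factory=dict)

    @classmethod
    def from_iterations(
        cls, window: str, accs: list[float], cms: list[pd.DataFrame], counts: dict
    ) -> "DecodingResult":
        accs_arr = np.asarray(accs, dtype=float)
        mean_cm = sum(cms) / len(cms)
        return cls(
            window=window,
            per_iteration_accuracy=accs_arr,
            mean_accuracy=float(accs_arr.mean()),
            confusion=mean_cm,
            n_trials_per_class=counts,
        )


@dataclass
class GenMatrix:
    """Train-time x test-time accuracy matrix."""

    times_ms: np.ndarray  # bin centers
    accuracy: np.ndarray  # train bins x test bins, mean over iterations
    bin_width_ms: float
    n_iterations: int

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{t:.0f}" for t in self.times_ms]
        return pd.DataFrame(self.accuracy, index=labels, columns=labels)


def _class_counts(y: np.ndarray) -> dict:
    return {c: int((y == c).sum()) for c in sorted(set(y.tolist()), key=str)}


def _split_trials(
    y: np.ndarray, train_fraction: float, group_size: int, rng: np.random.Generator,
    context: str = "",
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified trial-level split; both partitions must support at least
    one pseudo-trial per class."""
    train_idx, test_idx = [], []
    for c in sorted(set(y.tolist()), key=str):
        idx = rng.permutation(np.flatnonzero(y == c))
        n_train = round(train_fraction * len(idx))
        n_train = min(max(n_train, group_size), len(idx) - group_size)
        if n_train < group_size or len(idx) - n_train < group_size:
            raise PipelineError(
                f"insufficient trials for class {c!r}{context}: {len(idx)} trials "
                f"cannot support group_size={group_size} on both partitions"
            )
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def _prepare_partition(
    X: np.ndarray, y: np.ndarray, group_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-trial averaging then stratified up-sampling, within one partition."""
    ps = make_pseudotrials(X, y, group_size=group_size, rng=rng)
    return stratify_upsample(ps.features, ps.labels, rng=rng)


def mean_accuracy(X: np.ndarray, y: np.ndarray, cv: CvScheme) -> float:
    """Mean cross-validated accuracy only (no confusion bookkeeping).

    Same resampling chain as :func:`decode_features`; used where only the
    scalar statistic is needed, e.g. inside permutation nulls.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    ss = np.random.SeedSequence(cv.seed)
    accs = np.empty(cv.n_iterations)
    for i, child in enumerate(ss.spawn(cv.n_iterations)):
        rng = np.random.default_rng(child)
        tr, te = _split_trials(y, cv.train_fraction, cv.group_size, rng)
        Xtr, ytr = _prepare_partition(X[tr], y[tr], cv.group_size, rng)
        Xte, yte = _prepare_partition(X[te], y[te], cv.group_size, rng)
        mu = Xtr.mean(axis=0)
        model = lda.fit(Xtr - mu, ytr, shrinkage=cv.shrinkage)
        pred, _ = lda.predict(model, Xte - mu)
        accs[i] = (pred == yte).mean()
    return float(accs.mean())


def decode_features(
    X: np.ndarray,
    y: np.ndarray,
    cv: CvScheme,
    window: str = "features",
) -> DecodingResult:
    """Run the full iterated pipeline on a trials x features matrix."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    ss = np.random.SeedSequence(cv.seed)
    accs, cms = [], []
    classes = sorted(set(y.tolist()), key=str)
    for child in ss.spawn(cv.n_iterations):
        rng = np.random.default_rng(child)
        tr, te = _split_trials(y, cv.train_fraction, cv.group_size, rng,
                               context=f" in window {window!r}")
        Xtr, ytr = _prepare_partition(X[tr], y[tr], cv.group_size, rng)
        Xte, yte = _prepare_partition(X[te], y[te], cv.group_size, rng)
        mu = Xtr.mean(axis=0)
        model = lda.fit(Xtr - mu, ytr, shrinkage=cv.shrinkage)
        pred, _ = lda.predict(model, Xte - mu)
        acc, cm = lda.accuracy_and_confusion(yte, pred, class_labels=classes)
        accs.append(acc)
        cms.append(cm)
    return DecodingResult.from_iterations(window, accs, cms, _class_counts(y))


def decode_window(
    ep: EpochSet, window_ms: tuple[float, float], cv: CvScheme, name: str | None = None
) -> DecodingResult:
    """Time-averaged decoding in one window."""
    X = window_average(ep, window_ms)
    name = name or f"[{window_ms[0]:.0f}, {window_ms[1]:.0f}) ms"
    return decode_features(X, ep.labels, cv, window=name)


def decode_timeavg_all(
    ep: EpochSet,
    cv: CvScheme,
    windows: dict[str, tuple[float, float]] | None = None,
) -> dict[str, DecodingResult]:
    """Baseline / Sensory / Delay time-averaged decoding."""
    windows = windows or DEFAULT_WINDOWS
    return {
        name: decode_window(ep, win, cv, name=name) for name, win in windows.items()
    }


def _bin_epochs(ep: EpochSet, bin_width_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Average samples into contiguous time bins.

    Returns ``(X_binned, centers_ms)`` with X shaped trials x bins x channels.
    """
    spb_f = bin_width_ms * ep.fs_hz / 1000.0
    spb = round(spb_f)
    if spb < 1 or abs(spb_f - spb) > 1e-6:
        raise ConfigurationError(
            f"bin width {bin_width_ms} ms is not an integer number of samples at fs={ep.fs_hz}"
        )
    n_bins = ep.data.shape[2] // spb
    if n_bins < 2:
        raise ConfigurationError("bin width leaves fewer than 2 bins in the epoch")
    trimmed = ep.data[:, :, : n_bins * spb]
    binned = trimmed.reshape(ep.n_trials, ep.n_channels, n_bins, spb).mean(axis=3)
    centers = ep.times_ms[0] + (np.arange(n_bins) + 0.5) * bin_width_ms
    return np.transpose(binned, (0, 2, 1)).astype(np.float64), centers


def temporal_generalization(
    ep: EpochSet, bin_width_ms: float, cv: CvScheme
) -> GenMatrix:
    """Train on each time bin, test on every bin of the held-out partition.

    One trial-level split per iteration is shared by all bins, and the
    pseudo-trial groupings and up-sampling indices within each partition
    are likewise drawn once per iteration and reused across bins, so bins
    differ only in the time window the features summarize.
    """
    Xb, centers = _bin_epochs(ep, bin_width_ms)
    y = np.asarray(ep.labels, dtype=object)
    n_bins = Xb.shape[1]
    ss = np.random.SeedSequence(cv.seed)
    acc_sum = np.zeros((n_bins, n_bins))
    for child in ss.spawn(cv.n_iterations):
        rng = np.random.default_rng(child)
        tr, te = _split_trials(y, cv.train_fraction, cv.group_size, rng,
                               context=" in temporal generalization")
        # pseudo-trials for all bins at once (same trial groups per bin)
        ps_tr = make_pseudotrials(Xb[tr], y[tr], cv.group_size, rng)
        ps_te = make_pseudotrials(Xb[te], y[te], cv.group_size, rng)
        Ftr, ytr = stratify_upsample(ps_tr.features, ps_tr.labels, rng)
        Fte, yte = stratify_upsample(ps_te.features, ps_te.labels, rng)
        # per-bin demeaning with training-partition means
        mu = Ftr.mean(axis=0)  # bins x channels
        Ftr = Ftr - mu
        Fte = Fte - mu
        for t in range(n_bins):
            model = lda.fit(Ftr[:, t, :], ytr, shrinkage=cv.shrinkage)
            # score all test bins in one shot: (n_te, bins, ch) @ (ch, k)
            scores = np.einsum("ibf,kf->ibk", Fte, model.weights) + model.biases
            pred = model.class_labels[np.argmax(scores, axis=2)]  # n_te x bins
            acc_sum[t] += (pred == yte[:, None]).mean(axis=0)
    return GenMatrix(
        times_ms=centers,
        accuracy=acc_sum / cv.n_iterations,
        bin_width_ms=float(bin_width_ms),
        n_iterations=cv.n_iterations,
    )


def _half_masks(ep: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    if "block" not in ep.trial_meta.columns:
        raise ConfigurationError("split-half analyses require 'block' trial metadata")
    blocks = ep.trial_meta["block"].to_numpy()
    n_blocks = int(blocks.max())
    early = blocks <= n_blocks // 2
    return early, ~early


def split_half_decode(
    ep: EpochSet,
    cv: CvScheme,
    mode: str = "timeavg",
    windows: dict[str, tuple[float, float]] | None = None,
    bin_width_ms: float = 50.0,
) -> dict[str, dict[str, DecodingResult] | GenMatrix]:
    """Run the full analysis independently on the early and late session halves."""
    early, late = _half_masks(ep)
    out: dict = {}
    for name, mask in (("early", early), ("late", late)):
        half = ep.select(mask)
        if mode == "timeavg":
            out[name] = decode_timeavg_all(half, cv, windows=windows)
        elif mode == "tempgen":
            out[name] = temporal_generalization(half, bin_width_ms, cv)
        else:
            raise ConfigurationError(f"unknown split-half mode {mode!r}")
    return out


def cross_decode(
    train_ep: EpochSet,
    test_ep: EpochSet,
    cv: CvScheme,
    windows: dict[str, tuple[float, float]] | None = None,
) -> dict[str, DecodingResult]:
    """Train on one dataset (e.g. the early session half), test on another.

    The partitions are disjoint by construction, so there is no trial-level
    split; instead each iteration redraws the pseudo-trial groupings and
    up-sampling on both sides to yield an accuracy distribution comparable
    to the within-half analyses.
    """
    if train_ep.n_channels != test_ep.n_channels:
        raise ConfigurationError("channel montage mismatch between train and test sets")
    if len(train_ep.times_ms) != len(test_ep.times_ms) or not np.allclose(
        train_ep.times_ms, test_ep.times_ms
    ):
        raise ConfigurationError("epoch time grids differ between train and test sets")
    windows = windows or DEFAULT_WINDOWS
    out = {}
    for name, win in windows.items():
        Xtr_all = window_average(train_ep, win)
        Xte_all = window_average(test_ep, win)
        ytr_all = np.asarray(train_ep.labels, dtype=object)
        yte_all = np.asarray(test_ep.labels, dtype=object)
        classes = sorted(set(ytr_all.tolist()) | set(yte_all.tolist()), key=str)
        ss = np.random.SeedSequence(cv.seed)
        accs, cms = [], []
        for child in ss.spawn(cv.n_iterations):
            rng = np.random.default_rng(child)
            Xtr, ytr = _prepare_partition(Xtr_all, ytr_all, cv.group_size, rng)
            Xte, yte = _prepare_partition(Xte_all, yte_all, cv.group_size, rng)
            mu = Xtr.mean(axis=0)
            model = lda.fit(Xtr - mu, ytr, shrinkage=cv.shrinkage)
            pred, _ = lda.predict(model, Xte - mu)
            acc, cm = lda.accuracy_and_confusion(yte, pred, class_labels=classes)
            accs.append(acc)
            cms.append(cm)
        out[name] = DecodingResult.from_iterations(
            name, accs, cms, _class_counts(ytr_all)
        )
    return out
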