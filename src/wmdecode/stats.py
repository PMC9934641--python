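"""Group-level inference over per-subject decoding accuracies.

Provides the tests used to interpret the decoding pipeline at the cohort
level: one-sided t-tests against the 1/3 theoretical chance level with
optional Bonferroni correction across windows or time bins, a
subject-wise permutation test (labels shuffled independently within each
subject, group mean accuracy recomputed per permutation), the paired
Sensory-greater-than-Delay comparison, the Sensory-Delay Pearson
correlation across subjects, and a linear regression of accuracy on age.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .decode import CvScheme, mean_accuracy
from .exceptions import ConfigurationError
from .preprocess import EpochSet
from .pseudotrials import window_average

logger = logging.getLogger(__name__)

CHANCE = 1.0 / 3.0

__all__ = [
    "CHANCE",
    "GroupStats",
    "PermutationNull",
    "ttest_vs_chance",
    "permutation_test",
    "paired_sensory_delay",
    "sensory_delay_correlation",
    "age_regression",
]


@dataclass
class GroupStats:
    test_name: str
    estimate: float
    test_statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    n_subjects: int
    alpha: float = 0.05
    correction: str = "none"
    direction: str = "greater"
    zero_variance: bool = False

    @property
    def significant(self) -> bool:
        return self.p_adjusted < self.alpha


@dataclass
class PermutationNull:
    observed_group_stat: float
    null_distribution: np.ndarray
    p_perm: float
    n_permutations: int
    alpha: float = 0.05
    cv_iterations_used: int = 0

    @property
    def significant(self) -> bool:
        return self.p_perm < self.alpha


def _bonferroni(p: float, n_tests: int) -> float:
    return float(min(1.0, p * max(n_tests, 1)))


def ttest_vs_chance(
    accuracies: np.ndarray,
    chance: float = CHANCE,
    n_tests: int = 1,
    alpha: float = 0.05,
    test_name: str = "vs_chance",
) -> GroupStats:
    """One-sample, one-sided (greater) t-test of per-subject mean
    accuracies against theoretical chance, Bonferroni-corrected for
    ``n_tests`` simultaneous windows or bins."""
    acc = np.asarray(accuracies, dtype=float)
    if len(acc) < 2:
        raise ConfigurationError("need at least 2 subjects")
    mean = float(acc.mean())
    if acc.std(ddof=1) == 0.0:
        # degenerate: decide by the sign of the mean difference, flagged
        p = 0.0 if mean > chance else 1.0
        logger.warning("ttest_vs_chance: zero variance across subjects; exact decision by sign")
        return GroupStats(
            test_name=test_name, estimate=mean, test_statistic=np.inf if mean > chance else -np.inf,
            df=len(acc) - 1, p_raw=p, p_adjusted=_bonferroni(p, n_tests),
            n_subjects=len(acc), alpha=alpha,
            correction="bonferroni" if n_tests > 1 else "none",
            zero_variance=True,
        )
    res = sps.ttest_1samp(acc, chance, alternative="greater")
    return GroupStats(
        test_name=test_name,
        estimate=mean,
        test_statistic=float(res.statistic),
        df=float(len(acc) - 1),
        p_raw=float(res.pvalue),
        p_adjusted=_bonferroni(float(res.pvalue), n_tests),
        n_subjects=len(acc),
        alpha=alpha,
        correction="bonferroni" if n_tests > 1 else "none",
    )


def permutation_test(
    epochsets: list[EpochSet],
    window_ms: tuple[float, float],
    n_perm: int = 1000,
    seed: int = 0,
    cv: CvScheme | None = None,
    alpha: float = 0.05,
    decode_fn=None,
) -> PermutationNull:
    """Subject-wise permutation test of group mean decoding accuracy.

    Each permutation independently shuffles every subject's trial labels
    and recomputes that subject's mean accuracy with the (typically
    reduced-replication) scheme ``cv``; the group statistic is the
    cross-subject mean.  The p-value uses the add-one formula
    ``(1 + #{null >= observed}) / (1 + n_perm)`` so it is never exactly 0.

    ``decode_fn(X, y, cv, seed)`` may be injected to substitute the
    per-subject statistic (used for fast calibration checks); the default
    runs the real pipeline via :func:`wmdecode.decode.mean_accuracy`.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives unstable permutation p-values",
                      stacklevel=2)
    cv = cv or CvScheme(n_iterations=10)
    if decode_fn is None:
        def decode_fn(X, y, cv_, seed_):
            return mean_accuracy(X, y, replace(cv_, seed=seed_))

    feats = [(window_average(ep, window_ms), np.asarray(ep.labels, dtype=object))
             for ep in epochsets]
    rng = np.random.default_rng(seed)

    observed = float(np.mean([
        decode_fn(X, y, cv, int(rng.integers(2**31))) for X, y in feats
    ]))
    null = np.empty(n_perm)
    for j in range(n_perm):
        vals = []
        for X, y in feats:
            y_perm = rng.permutation(y)
            vals.append(decode_fn(X, y_perm, cv, int(rng.integers(2**31))))
        null[j] = np.mean(vals)
    p = float((1 + np.sum(null >= observed)) / (1 + n_perm))
    logger.info(
        "permutation_test: observed=%.4f, p=%.4g (N=%d, cv_iterations=%d)",
        observed, p, n_perm, cv.n_iterations,
    )
    return PermutationNull(
        observed_group_stat=observed,
        null_distribution=null,
        p_perm=p,
        n_permutations=n_perm,
        alpha=alpha,
        cv_iterations_used=cv.n_iterations,
    )


def paired_sensory_delay(
    sensory: np.ndarray, delay: np.ndarray, alpha: float = 0.05
) -> GroupStats:
    """Paired right-tailed t-test of Sensory > Delay accuracy."""
    s = np.asarray(sensory, dtype=float)
    d = np.asarray(delay, dtype=float)
    if s.shape != d.shape:
        raise ConfigurationError("sensory and delay vectors must have equal length")
    if len(s) < 2:
        raise ConfigurationError("need at least 2 subjects")
    diff = s - d
    if diff.std(ddof=1) == 0.0:
        mean = float(diff.mean())
        p = 0.0 if mean > 0 else 1.0
        if mean == 0.0:
            p = 1.0
        return GroupStats(
            test_name="sensory_vs_delay", estimate=mean,
            test_statistic=0.0 if mean == 0 else np.sign(mean) * np.inf,
            df=len(s) - 1, p_raw=p, p_adjusted=p, n_subjects=len(s),
            alpha=alpha, zero_variance=True,
        )
    res = sps.ttest_rel(s, d, alternative="greater")
    return GroupStats(
        test_name="sensory_vs_delay",
        estimate=float(diff.mean()),
        test_statistic=float(res.statistic),
        df=float(len(s) - 1),
        p_raw=float(res.pvalue),
        p_adjusted=float(res.pvalue),
        n_subjects=len(s),
        alpha=alpha,
    )


def sensory_delay_correlation(
    sensory: np.ndarray, delay: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of Sensory vs Delay accuracy."""
    s = np.asarray(sensory, dtype=float)
    d = np.asarray(delay, dtype=float)
    if len(s) != len(d) or len(s) < 3:
        raise ConfigurationError("need paired vectors of length >= 3")
    if np.allclose(s.std(), 0.0) or np.allclose(d.std(), 0.0):
        raise ConfigurationError("zero variance: correlation undefined")
    r, p = sps.pearsonr(s, d)
    return float(r), float(p)


def age_regression(
    ages_months: np.ndarray, accuracies: np.ndarray, window: str = ""
) -> dict:
    """OLS of accuracy on age; reports R^2, slope, and the F-test p-value
    (identical to the slope t-test for a single regressor)."""
    x = np.asarray(ages_months, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ConfigurationError("need paired vectors of length >= 3")
    if np.allclose(x.std(), 0.0):
        raise ConfigurationError("constant age: regression undefined")
    res = sps.linregress(x, y)
    return {
        "window": window,
        "r_squared": float(res.rvalue**2),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "p": float(res.pvalue),
        "n": len(x),
    }
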