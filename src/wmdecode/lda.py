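"""Multiclass linear discriminant analysis with shrinkage-regularized
pooled covariance.

The classifier assumes class-conditional Gaussians sharing one covariance.
Because the channel count (64) can exceed the pseudo-trial count inside a
cross-validation fold, the pooled within-class covariance S is shrunk
toward a scaled identity,

    Sigma_hat = (1 - lambda) * S + lambda * (tr(S)/p) * I,

with lambda chosen by the Ledoit-Wolf analytic estimator (closed form
below) unless fixed by the caller.  Class k scores test point x with the
affine discriminant

    g_k(x) = w_k^T x + b_k,   w_k = Sigma_hat^{-1} mu_k,
    b_k = -0.5 * mu_k^T Sigma_hat^{-1} mu_k + log pi_k,

using empirical priors pi_k; the predicted label is the argmax, with ties
broken deterministically toward the smallest class index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["LdaModel", "fit", "predict", "ledoit_wolf_shrinkage", "accuracy_and_confusion"]


@dataclass
class LdaModel:
    class_labels: np.ndarray
    class_means: np.ndarray  # classes x features
    pooled_cov: np.ndarray  # features x features, after shrinkage
    shrinkage_lambda: float
    weights: np.ndarray  # classes x features
    biases: np.ndarray  # classes
    priors: np.ndarray

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def to_dict(self) -> dict:
        """JSON-serializable summary for audit."""
        return {
            "class_labels": [str(c) for c in self.class_labels],
            "shrinkage_lambda": self.shrinkage_lambda,
            "class_means": self.class_means.tolist(),
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
            "priors": self.priors.tolist(),
        }


def ledoit_wolf_shrinkage(Z: np.ndarray) -> float:
    """Ledoit-Wolf optimal shrinkage toward (tr(S)/p) * I.

    ``Z`` holds mean-free observations (rows); with S = Z^T Z / n the
    estimator is lambda* = min(1, beta^2 / delta^2) where

        delta^2 = ||S - (tr S / p) I||_F^2 / p
        beta^2  = min(delta^2,
                      (sum_i ||z_i||^4 - n ||S||_F^2) / (n^2 p)).
    """
    Z = np.asarray(Z, dtype=np.float64)
    n, p = Z.shape
    if n < 2:
        return 1.0
    S = Z.T @ Z / n
    mu = np.trace(S) / p
    delta2 = np.sum((S - mu * np.eye(p)) ** 2) / p
    if delta2 <= 0:
        return 0.0
    beta2 = (np.sum(np.sum(Z**2, axis=1) ** 2) - n * np.sum(S**2)) / (n**2 * p)
    beta2 = min(beta2, delta2)
    return float(np.clip(beta2 / delta2, 0.0, 1.0))


def fit(
    X: np.ndarray,
    y: np.ndarray,
    shrinkage: float | str = "auto",
) -> LdaModel:
    """Fit the shrinkage-LDA model.

    ``shrinkage`` is ``"auto"`` (Ledoit-Wolf) or a fixed value in [0, 1].
    With lambda = 0 a singular pooled covariance raises, instructing the
    caller to use nonzero shrinkage.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()), key=str)
    if len(classes) < 2:
        raise ConfigurationError("need at least 2 classes")
    n, p = X.shape
    means = np.empty((len(classes), p))
    priors = np.empty(len(classes))
    Z = np.empty_like(X)
    for k, c in enumerate(classes):
        idx = np.flatnonzero(y == c)
        if len(idx) < 2:
            raise ConfigurationError(f"class {c!r} has fewer than 2 samples")
        means[k] = X[idx].mean(axis=0)
        priors[k] = len(idx) / n
        Z[idx] = X[idx] - means[k]

    S = Z.T @ Z / max(n - len(classes), 1)
    if shrinkage == "auto":
        lam = ledoit_wolf_shrinkage(Z)
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ConfigurationError("shrinkage must be in [0, 1] or 'auto'")
    nu = np.trace(S) / p
    sigma = (1.0 - lam) * S + lam * nu * np.eye(p)

    try:
        # solve rather than invert; raises on exact singularity
        weights = np.linalg.solve(sigma, means.T).T
    except np.linalg.LinAlgError as err:
        raise ConfigurationError(
            "pooled covariance is singular at shrinkage lambda="
            f"{lam}; use nonzero shrinkage (e.g. 'auto')"
        ) from err
    # guard near-singular solves that silently produce non-finite weights
    if not np.all(np.isfinite(weights)):
        raise ConfigurationError(
            f"pooled covariance is numerically singular at lambda={lam}; "
            "use nonzero shrinkage (e.g. 'auto')"
        )
    biases = -0.5 * np.einsum("kf,kf->k", means, weights) + np.log(priors)
    return LdaModel(
        class_labels=np.array(classes, dtype=object),
        class_means=means,
        pooled_cov=sigma,
        shrinkage_lambda=lam,
        weights=weights,
        biases=biases,
        priors=priors,
    )


def predict(model: LdaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and per-class discriminant scores for ``X``.

    Ties are broken toward the smallest class index (np.argmax semantics)
    and logged at DEBUG level.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ConfigurationError(
            f"feature dimension mismatch: got {X.shape}, expected (*, {model.n_features})"
        )
    scores = X @ model.weights.T + model.biases
    top = scores.max(axis=1, keepdims=True)
    ties = (scores == top).sum(axis=1) > 1
    if ties.any():
        logger.debug("predict: %d tie(s) broken toward the smallest class index", ties.sum())
    labels = model.class_labels[np.argmax(scores, axis=1)]
    return labels, scores


def accuracy_and_confusion(
    true_y: np.ndarray,
    pred_y: np.ndarray,
    class_labels: np.ndarray | list | None = None,
) -> tuple[float, pd.DataFrame]:
    """Overall accuracy and the row-normalized confusion matrix.

    Row r, column c holds the fraction of true-class-r items predicted as
    class c, so rows sum to 1.  A class listed in ``class_labels`` but
    absent from ``true_y`` would have an undefined row and raises rather
    than silently emitting NaN.
    """
    true_y = np.asarray(true_y)
    pred_y = np.asarray(pred_y)
    if len(true_y) != len(pred_y):
        raise ConfigurationError("true_y and pred_y must have equal length")
    classes = (
        sorted(set(true_y.tolist()) | set(pred_y.tolist()), key=str)
        if class_labels is None
        else list(class_labels)
    )
    missing = [c for c in classes if not np.any(true_y == c)]
    if missing:
        raise ConfigurationError(f"class(es) {missing} absent from true_y: confusion row undefined")
    cm = np.zeros((len(classes), len(classes)))
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(true_y, pred_y):
        cm[index[t], index[p]] += 1
    cm /= cm.sum(axis=1, keepdims=True)
    acc = float((true_y == pred_y).mean())
    return acc, pd.DataFrame(cm, index=classes, columns=classes)
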