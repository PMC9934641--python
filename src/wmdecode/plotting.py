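"""Minimal result figures: accuracy violins and temporal-generalization heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .decode import GenMatrix
from .stats import CHANCE

__all__ = ["accuracy_violin", "tempgen_heatmap"]


def accuracy_violin(per_window: dict[str, np.ndarray], ax=None):
    """Violin of per-subject mean accuracies per analysis window."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    names = list(per_window)
    data = [np.asarray(per_window[n], dtype=float) for n in names]
    ax.violinplot(data, showmeans=True, showmedians=True)
    for i, vals in enumerate(data, start=1):
        ax.scatter(np.full(len(vals), i), vals, s=8, color="k", alpha=0.5, zorder=3)
    ax.axhline(CHANCE, ls="-.", color="k", lw=0.8)
    ax.set_xticks(range(1, len(names) + 1), names)
    ax.set_ylabel("decoding accuracy")
    return ax.figure


def tempgen_heatmap(gm: GenMatrix, mask: np.ndarray | None = None, ax=None):
    """Train-time x test-time accuracy map; non-significant cells grayed out."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 3.6))
    acc = gm.accuracy.copy()
    extent = [gm.times_ms[0], gm.times_ms[-1], gm.times_ms[0], gm.times_ms[-1]]
    im = ax.imshow(acc, origin="lower", extent=extent, aspect="equal", cmap="viridis")
    if mask is not None:
        gray = np.where(mask, np.nan, 1.0)
        ax.imshow(gray, origin="lower", extent=extent, aspect="equal",
                  cmap="Greys", vmin=0, vmax=2, alpha=0.6)
    ax.set_xlabel("test time (ms)")
    ax.set_ylabel("train time (ms)")
    ax.figure.colorbar(im, ax=ax, label="accuracy")
    return ax.figure
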