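"""Plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np
import scipy.stats


def _ellipse_points(mean, cov, prob: float, n: int = 100):
    """Boundary of the Gaussian probability ellipse at the given coverage."""
    radius2 = scipy.stats.chi2.ppf(prob, df=2)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0, None)
    t = np.linspace(0, 2 * np.pi, n)
    circle = np.column_stack([np.cos(t), np.sin(t)])
    return mean + circle * np.sqrt(radius2 * vals) @ vecs.T


def cva_scatter(results, ax=None, ellipse_prob: float = 0.90):
    """Scatter of the first two canonical axes with per-group probability
    ellipses (default 90% coverage)."""
    import matplotlib
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    scores = results.scores
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 canonical axes to plot")
    labels = results.score_labels
    cmap = matplotlib.colormaps["tab20"]
    for i, name in enumerate(results.group_names):
        pts = scores[(labels == name).to_numpy()][:, :2]
        color = cmap(i % 20)
        ax.scatter(pts[:, 0], pts[:, 1], s=12, color=color, label=name, alpha=0.7)
        if len(pts) > 2:
            cov = np.cov(pts.T)
            ring = _ellipse_points(pts.mean(axis=0), cov, ellipse_prob)
            ax.plot(ring[:, 0], ring[:, 1], color=color, lw=1)
    ax.set_xlabel("CV1")
    ax.set_ylabel("CV2")
    ax.legend(fontsize=7, ncol=2)
    ax.set_title(f"Canonical variate scores ({100 * ellipse_prob:.0f}% ellipses)")
    return ax
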