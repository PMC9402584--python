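"""Minimal plots: per-clade density of ancestral estimates, fin outlines."""

from __future__ import annotations

from typing import Mapping

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["density_plot", "outline_plot"]


def density_plot(distributions: Mapping[str, np.ndarray], path, xlabel="speed (BL/s)"):
    """Stacked density (KDE) plot of per-clade ancestral estimates."""
    from scipy import stats

    fig, ax = plt.subplots(figsize=(6, 0.9 * max(len(distributions), 2) + 1))
    names = list(distributions)
    for i, name in enumerate(names):
        vals = np.asarray(distributions[name], dtype=float)
        if len(vals) < 2 or np.ptp(vals) < 1e-12:
            ax.plot([vals.mean()] * 2, [i, i + 0.8], lw=2)
        else:
            kde = stats.gaussian_kde(vals)
            grid = np.linspace(vals.min() - 3 * vals.std(), vals.max() + 3 * vals.std(), 200)
            dens = kde(grid)
            ax.fill_between(grid, i, i + 0.8 * dens / dens.max(), alpha=0.6)
        ax.text(ax.get_xlim()[0], i + 0.4, name, fontsize=8, va="center")
    ax.set_yticks([])
    ax.set_xlabel(xlabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def outline_plot(outlines: Mapping[str, np.ndarray], path):
    """Overlay of (aligned) fin outlines or landmark configurations."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, pts in outlines.items():
        pts = np.asarray(pts)
        closed = np.vstack([pts, pts[:1]])
        ax.plot(closed[:, 0], closed[:, 1], lw=0.8, label=name)
    ax.set_aspect("equal")
    if len(outlines) <= 8:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
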