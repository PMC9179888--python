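"""Manhattan-style and LD-decay plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_ALT = ("#1f77b4", "#ff7f0e")  # alternating chromosome colors


def _genome_x(chrom: np.ndarray, pos: np.ndarray):
    """Concatenated genome coordinate + per-chromosome tick positions."""
    x = np.zeros(len(pos), dtype=float)
    ticks, labels = [], []
    offset = 0
    for c in pd.unique(chrom):
        sel = chrom == c
        x[sel] = pos[sel] + offset
        ticks.append(offset + pos[sel].mean())
        labels.append(str(c))
        offset += pos[sel].max()
    return x, ticks, labels


def manhattan(chrom, pos, values, thresholds=(), ylabel="score", path=None,
              title=None):
    """Genome-wide scatter with alternating chromosome colors and
    horizontal threshold lines."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    values = np.asarray(values, dtype=float)
    x, ticks, labels = _genome_x(chrom, pos)
    fig, ax = plt.subplots(figsize=(12, 4))
    for i, c in enumerate(pd.unique(chrom)):
        sel = chrom == c
        ax.scatter(x[sel], values[sel], s=4, color=_ALT[i % 2], rasterized=True)
    for t in np.atleast_1d(thresholds):
        ax.axhline(float(t), color="crimson", lw=1, ls="--")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def decay_plot(curves: dict[str, pd.DataFrame], path=None):
    """Overlayed LD-decay curves, one line per population."""
    colors = {0: "red", 1: "blue"}
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for i, (name, curve) in enumerate(curves.items()):
        ax.plot(curve.iloc[:, 0] / 1e3, curve["mean_r2"],
                color=colors.get(i, None), lw=1, label=name, alpha=0.8)
    ax.set_xlabel("inter-marker distance (kb)")
    ax.set_ylabel("mean $r^2$")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
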