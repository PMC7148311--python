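"""Figure helpers: RDA triplot and enrichment heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .envassoc import RDAResult


def rda_triplot(result: RDAResult, path: str | Path, scale: float = 1.0) -> None:
    """Correlation-biplot style triplot of the first two constrained axes."""
    fig, ax = plt.subplots(figsize=(7, 7))
    axes = list(result.eigenvalues.index[:2])
    if len(axes) < 2:
        axes = axes + axes  # degenerate single-axis case: plot axis 1 twice
    sx, sy = result.sample_scores[axes[0]], result.sample_scores[axes[1]]
    ax.scatter(sx, sy, s=12, c="grey", alpha=0.6, label="samples")
    for name, row in result.response_scores.iterrows():
        ax.annotate(str(name), (row[axes[0]] * scale, row[axes[1]] * scale),
                    color="tab:blue", fontsize=9, fontweight="bold")
    arrow_scale = max(abs(sx).max(), abs(sy).max())
    for name, row in result.biplot_scores.iterrows():
        dx, dy = row[axes[0]] * arrow_scale, row[axes[1]] * arrow_scale
        ax.annotate("", xy=(dx, dy), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="black", lw=0.8))
        ax.annotate(str(name), (dx * 1.05, dy * 1.05), fontsize=8)
    tot = result.eigenvalues.sum()
    labels = [
        f"{a} ({100 * result.eigenvalues[a] / tot:.0f}% of constrained)" for a in axes[:2]
    ]
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[-1])
    ax.axhline(0, color="k", lw=0.3)
    ax.axvline(0, color="k", lw=0.3)
    ax.set_title(
        f"RDA triplot - constrained fraction {result.constrained_fraction:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def enrichment_heatmap(
    odds: pd.DataFrame, significant: pd.DataFrame, analyzed: pd.DataFrame,
    path: str | Path,
) -> None:
    """Log odds-ratio heatmap; grey = not analyzed, boxed = significant."""
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * odds.shape[1] + 2), max(3, 0.22 * odds.shape[0] + 1))
    )
    raw = odds.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        vals = np.where(raw > 0, np.log2(np.where(raw > 0, raw, 1.0)), np.nan)
    vals = np.where(analyzed.to_numpy(), vals, np.nan)
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("lightgrey")
    lim = np.nanmax(np.abs(vals[np.isfinite(vals)])) if np.isfinite(vals).any() else 1
    im = ax.imshow(vals, aspect="auto", cmap=cmap, vmin=-lim, vmax=lim)
    sig = significant.to_numpy()
    for i, j in zip(*np.nonzero(sig)):
        ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False, lw=1.2))
    ax.set_yticks(range(odds.shape[0]), odds.index, fontsize=6)
    ax.set_xticks(
        range(odds.shape[1]),
        [f"{s}|M{m}" for s, m in odds.columns],
        rotation=90, fontsize=6,
    )
    fig.colorbar(im, ax=ax, label="log2 odds ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
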