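"""Optional diagnostic plots, colored by functional gene category."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .bias_analysis import EncRatioHistogram, NeutralityFit
from .codon_metrics import enc_expected

__all__ = ["enc_plot", "pr2_plot", "neutrality_plot", "enc_ratio_plot"]

_CATEGORY_COLORS = {
    "photosynthesis": "#2ca02c",
    "self-replication": "#1f77b4",
    "other": "#ff7f0e",
    "unknown": "#7f7f7f",
}


def _scatter_by_category(ax, table: pd.DataFrame, x: str, y: str) -> None:
    for category, sub in table.groupby("category"):
        ax.scatter(
            sub[x], sub[y], s=18, alpha=0.8,
            color=_CATEGORY_COLORS.get(category, "#000000"), label=category,
        )
    ax.legend(fontsize=8)


def enc_plot(table: pd.DataFrame, path) -> Path:
    """ENC vs GC3 scatter with the mutation-pressure expectation curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    grid = np.linspace(0.0, 1.0, 200)
    ax.plot(grid, [enc_expected(g) for g in grid], "k-", lw=1, label="ENCexp")
    _scatter_by_category(ax, table.dropna(subset=["enc_obs"]), "gc3", "enc_obs")
    ax.set_xlabel("GC3")
    ax.set_ylabel("ENC")
    ax.set_ylim(15, 65)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def pr2_plot(table: pd.DataFrame, path) -> Path:
    """PR2 bias scatter with the parity centre lines at 0.5."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.axhline(0.5, color="k", lw=0.8)
    ax.axvline(0.5, color="k", lw=0.8)
    _scatter_by_category(ax, table.dropna(subset=["pr2_x", "pr2_y"]), "pr2_x", "pr2_y")
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def neutrality_plot(table: pd.DataFrame, fit: NeutralityFit, path) -> Path:
    """GC12 vs GC3 scatter with the fitted regression and the diagonal."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    _scatter_by_category(ax, table, "gc3", "gc12")
    grid = np.linspace(table["gc3"].min(), table["gc3"].max(), 2)
    ax.plot(grid, fit.intercept + fit.slope * grid, "k-", lw=1.5,
            label=f"slope={fit.slope:.3g}, $R^2$={fit.r_squared:.3g}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def enc_ratio_plot(hist: EncRatioHistogram, path) -> Path:
    """Bar chart of the ENC-ratio distribution around the central band."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    edges = np.asarray(hist.bin_edges)
    centers = (edges[:-1] + edges[1:]) / 2
    widths = np.diff(edges) * 0.9
    ax.bar(centers, hist.counts, width=widths, color="#1f77b4")
    ax.set_xlabel("ENC ratio (ENCexp − ENCobs) / ENCexp")
    ax.set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
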