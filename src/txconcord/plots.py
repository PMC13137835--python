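"""Plot rendering from serialized report tables.

Both entry points consume the TSV files the pipeline wrote — regenerating a
figure never re-runs any statistics.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_lollipop", "plot_heatmap"]


def plot_lollipop(table_tsv, out_path) -> None:
    """Two-sided lollipop plot: convergent pathways extend left, divergent
    right, stem length -log10(adjusted p)."""
    df = pd.read_csv(table_tsv, sep="\t")
    fig, ax = plt.subplots(figsize=(7, max(2, 0.35 * max(len(df), 1))))
    if len(df):
        df = df.copy()
        df["signed"] = np.where(df["side"] == "convergent",
                                -df["neg_log10_padj"], df["neg_log10_padj"])
        df = df.sort_values(["side", "neg_log10_padj"])
        y = np.arange(len(df))
        colors = np.where(df["side"] == "convergent", "#1f77b4", "#d62728")
        ax.hlines(y, 0, df["signed"], color=colors, lw=1.5)
        ax.plot(df["signed"], y, "o", color="black", ms=4)
        ax.set_yticks(y)
        ax.set_yticklabels(df["set_name"], fontsize=7)
        ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("-log10(p.adjust)   (convergent <- | -> divergent)")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_heatmap(zscore_tsv, out_path, max_genes: int = 100) -> None:
    """Heat map of row z-scored expression (top rows by variance)."""
    df = pd.read_csv(zscore_tsv, sep="\t", index_col=0)
    if len(df) > max_genes:
        df = df.loc[df.var(axis=1).sort_values(ascending=False).index[:max_genes]]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.08 * len(df))))
    im = ax.imshow(df.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(df.shape[1]))
    ax.set_xticklabels(df.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(df)} genes (z-score)")
    fig.colorbar(im, ax=ax, shrink=0.6, label="z-score")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
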