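"""Genome-scan plot: per-chromosome mean delta-SNP-index with threshold."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_scan"]


def plot_scan(windows: pd.DataFrame, threshold: float, path: str | Path) -> None:
    """One panel per chromosome: black window-mean line, red dashed threshold."""
    chroms = list(windows["chrom"].unique())
    ncol = 4
    nrow = (len(chroms) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 1.9 * nrow),
                             sharey=True, squeeze=False)
    for ax in axes.flat[len(chroms):]:
        ax.set_visible(False)
    for ax, chrom in zip(axes.flat, chroms):
        sub = windows.loc[(windows["chrom"] == chrom) & (windows["n_snps"] > 0)]
        mid = (sub["start"] + sub["end"]) / 2e3
        ax.plot(mid, sub["mean_delta"], color="black", lw=0.8)
        ax.axhline(threshold, color="red", ls="--", lw=0.8)
        ax.axhline(0.0, color="grey", lw=0.4)
        ax.set_title(chrom, fontsize=8)
        ax.set_ylim(-1.05, 1.05)
        ax.tick_params(labelsize=7)
    fig.supxlabel("position (kb)", fontsize=9)
    fig.supylabel(r"mean $\Delta$(SNP-index)", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
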