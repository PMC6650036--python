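"""Basic plot export: fold-change profiles and correlation heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datatypes import AnovaResult, CqMatrix

__all__ = ["plot_profiles", "plot_correlation_heatmap"]


def plot_profiles(
    folds: pd.DataFrame,
    m: CqMatrix,
    anova: AnovaResult | None = None,
    out: str | Path | None = None,
):
    """Mean ± SD fold-change profile per gene across groups, one panel each."""
    group_labels = list(dict.fromkeys(m.groups))
    genes = list(folds.index)
    ncols = 4
    nrows = int(np.ceil(len(genes) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
                             squeeze=False)
    for ax in axes.flat[len(genes):]:
        ax.set_visible(False)
    for gene, ax in zip(genes, axes.flat):
        means, sds = [], []
        for g in group_labels:
            vals = folds.loc[gene, m.groups.index[m.groups == g]]
            means.append(vals.mean())
            sds.append(vals.std(ddof=1))
        ax.errorbar(range(len(group_labels)), means, yerr=sds, marker="o", capsize=3)
        ax.set_xticks(range(len(group_labels)), group_labels)
        title = gene
        if anova is not None and gene in anova.table.index:
            title += f" ({anova.table.loc[gene, 'stars']})"
        ax.set_title(title, fontsize=9)
        ax.set_ylabel("fold change")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def plot_correlation_heatmap(corr: pd.DataFrame, out: str | Path | None = None):
    """Gene × gene Pearson-r heatmap with the self-correlation diagonal masked."""
    fig, ax = plt.subplots(figsize=(0.6 * len(corr) + 2,) * 2)
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90)
    ax.set_yticks(range(len(corr)), corr.index)
    for i in range(len(corr)):
        ax.text(i, i, "X", ha="center", va="center")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
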