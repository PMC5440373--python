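"""Quick-look figures for enrichment curves and Manhattan tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .enrichment import EnrichmentCurves

_LABELS = {"qq": "empirical -log10 p", "fold": "fold enrichment", "tdr": "conditional TDR"}


def plot_curves(curves: EnrichmentCurves, which: str, path) -> None:
    """One panel of per-stratum curves versus nominal -log10 p."""
    data = getattr(curves, which)
    if data is None:
        raise ValueError(f"curves {which!r} not computed")
    fig, ax = plt.subplots(figsize=(5, 4))
    for t, y in data.items():
        label = "all SNPs" if t == 1.0 else f"p2 < {t:g}"
        ax.plot(curves.grid, y, label=label)
    if which == "qq":
        ax.plot(curves.grid, curves.grid, ls=":", color="grey", label="null")
    ax.set_xlabel("nominal -log10 p (primary trait)")
    ax.set_ylabel(_LABELS.get(which, which))
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_manhattan(table: pd.DataFrame, path, fdr_threshold: float = 0.05) -> None:
    """Conjunction-FDR Manhattan plot from a :func:`manhattan_export` table.

    Significant SNPs are enlarged; the strongest SNP per LD block is circled.
    """
    fig, ax = plt.subplots(figsize=(9, 3.5))
    offset = 0.0
    ticks, labels = [], []
    for chrom, grp in table.groupby("chrom", sort=False):
        x = grp["pos"].to_numpy(dtype=float) + offset
        size = np.where(grp["significant"], 18.0, 3.0)
        ax.scatter(x, grp["neg_log10_fdr"], s=size, alpha=0.7, linewidths=0)
        leads = grp["is_lead"].to_numpy()
        ax.scatter(x[leads], grp["neg_log10_fdr"].to_numpy()[leads],
                   s=50, facecolors="none", edgecolors="black", linewidths=0.8)
        ticks.append(offset + (x.max() - offset) / 2)
        labels.append(str(chrom))
        offset = x.max() + 1
    ax.axhline(-np.log10(fdr_threshold), color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 conjunction FDR")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
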