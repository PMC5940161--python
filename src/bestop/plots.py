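"""Figure rendering. Every figure has a TSV twin written by the CLI;
figures are never the only record of a number."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def sites_per_gene_hist(histogram: dict, path) -> None:
    """Bar chart of genes by number of targetable knockout sites."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ks = sorted(histogram)
    ax.bar(ks, [histogram[k] for k in ks], color="#4878A8")
    ax.set_xlabel("targetable knockout sites per gene")
    ax.set_ylabel("number of genes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def relative_position_hist(pos_hist: dict, path) -> None:
    """Stacked decile histogram of site positions within CDSs, per codon."""
    fig, ax = plt.subplots(figsize=(6, 4))
    deciles = np.arange(1, 11)
    bottom = np.zeros(10)
    for codon, counts in pos_hist.items():
        vals = np.array([counts.get(d, 0) for d in deciles], dtype=float)
        ax.bar(deciles, vals, bottom=bottom, label=codon)
        bottom += vals
    ax.set_xlabel("relative position in CDS (decile)")
    ax.set_ylabel("knockout sites")
    ax.legend(title="codon")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def per_position_heatmap(matrix: pd.DataFrame, path) -> None:
    """gRNA x position heatmap of per-position edit fractions.

    Darker cells mean more efficient substitution; positions where a
    gRNA has no C (NaN) are drawn grey.
    """
    fig, ax = plt.subplots(
        figsize=(8, max(2.0, 0.3 * len(matrix) + 1.5))
    )
    cmap = plt.get_cmap("Blues").copy()
    cmap.set_bad("#bbbbbb")
    data = np.ma.masked_invalid(matrix.to_numpy(dtype=float))
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=0)
    ax.set_xticks(range(20), labels=[str(i) for i in range(1, 21)])
    ax.set_yticks(range(len(matrix)), labels=list(matrix.index))
    ax.set_xlabel("protospacer position")
    fig.colorbar(im, ax=ax, label="fraction of reads edited")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def multiplex_bar(counts: dict, path) -> None:
    """Reads by number of simultaneous substitutions."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ks = sorted(counts)
    ax.bar(ks, [counts[k] for k in ks], color="#B85450")
    ax.set_yscale("log")
    ax.set_xlabel("base substitutions per read")
    ax.set_ylabel("reads")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def window_profile_bar(profile_frame: pd.DataFrame, path) -> None:
    """Editing-window probability per protospacer position."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(
        profile_frame["position"],
        profile_frame["probability"].fillna(0.0),
        color="#6A9955",
    )
    ax.set_xlabel("protospacer position")
    ax.set_ylabel("P(substitution | designed C)")
    ax.set_xticks(range(1, 21))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
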