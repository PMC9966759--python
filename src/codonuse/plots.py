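"""Figure helpers.  All plots are regenerable from the emitted TSV tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .codon_metrics import expected_enc_curve

__all__ = [
    "enc_gc3_plot",
    "deviation_ratio_histogram",
    "dinucleotide_ratio_plot",
    "pca_scatter",
]


def enc_gc3_plot(
    metrics: pd.DataFrame,
    path: str | Path,
    colour_by_subset: bool = False,
) -> None:
    """Scatter of per-gene (GC3, ENC) with the mutation-only expected curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    curve = expected_enc_curve()
    data = metrics.dropna(subset=["enc", "gc3"])
    if colour_by_subset and "subset_label" in data:
        bg = data[data["subset_label"].isna()]
        ax.scatter(bg["gc3"], bg["enc"], s=4, c="0.7", label="background")
        for label, fam in sorted(data.dropna(subset=["subset_label"]).groupby("subset_label")):
            ax.scatter(fam["gc3"], fam["enc"], s=10, label=str(label))
        ax.legend(fontsize=7)
    else:
        ax.scatter(data["gc3"], data["enc"], s=4, c="0.4")
    ax.plot(curve["gc3"], curve["enc_expected"], "k-", lw=1.2)
    ax.set_xlabel("GC3")
    ax.set_ylabel("ENC")
    ax.set_xlim(0, 1)
    ax.set_ylim(15, 62)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def deviation_ratio_histogram(metrics: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(metrics["deviation_ratio"].dropna(), bins=40, color="0.5")
    ax.axvline(0.0, color="k", lw=1)
    ax.set_xlabel("(ENC$_{exp}$ $-$ ENC$_{obs}$)/ENC$_{exp}$")
    ax.set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def dinucleotide_ratio_plot(ratios: pd.DataFrame, path: str | Path) -> None:
    """Observed/expected dinucleotide ratios per junction, reference line at 1."""
    junctions = sorted(ratios["junction"].unique())
    fig, axes = plt.subplots(
        1, len(junctions), figsize=(4 * len(junctions), 3.5), sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, j in zip(axes, junctions):
        sub = ratios[ratios["junction"] == j]
        ax.bar(sub["dinucleotide"], sub["ratio"], color="0.5")
        ax.axhline(1.0, color="k", lw=1)
        ax.set_title(f"junction {j}")
        ax.tick_params(axis="x", rotation=90, labelsize=7)
    axes[0].set_ylabel("observed / expected")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_scatter(
    scores: pd.DataFrame,
    gc3: pd.Series,
    variance_fraction: np.ndarray,
    path: str | Path,
) -> None:
    """PC1 and PC2 of the RSCU matrix against GC3."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for ax, pc in zip(axes, ("PC1", "PC2")):
        if pc not in scores:
            continue
        ax.scatter(gc3, scores[pc], s=4, c="0.4")
        k = int(pc[2:]) - 1
        frac = variance_fraction[k] if k < len(variance_fraction) else 0.0
        ax.set_xlabel("GC3")
        ax.set_ylabel(f"{pc} ({100 * frac:.1f}% var)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
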