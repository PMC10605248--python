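"""Matplotlib figures for the pipeline report."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .concordance import ContingencyTable2x2
from .expression import DEResult
from .optics import ConditionComparison
from .overlap import OverlapSweep

__all__ = [
    "plot_focal_curves",
    "plot_overlap_sweep",
    "plot_volcano",
    "plot_contingency",
]


def plot_focal_curves(comparison: ConditionComparison, path=None):
    """Per-condition mean focal-ratio curves with sd error bars."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, sub in comparison.mean_curves.groupby("condition", sort=False):
        ax.errorbar(sub["z_um"], sub["ratio_mean"], yerr=sub["ratio_sd"],
                    marker="o", ms=3, capsize=2, label=str(cond))
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("z (µm)")
    ax.set_ylabel("focal ratio R(z)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_overlap_sweep(sweep: OverlapSweep, path=None):
    """Observed vs expected-by-chance overlap across top fractions."""
    fig, ax = plt.subplots(figsize=(5, 4))
    t = sweep.table
    ax.plot(100 * t["x"], t["observed"], color="tab:blue", marker="o", ms=3,
            label="observed")
    ax.plot(100 * t["x"], t["expected"], color="grey", marker="s", ms=3,
            label="expected by chance")
    ax.set_xlabel("top x% most enriched")
    ax.set_ylabel("shared genes")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_volcano(de: DEResult, path=None):
    """log2 fold change vs -log10 FDR, DEGs highlighted."""
    fig, ax = plt.subplots(figsize=(5, 4))
    t = de.table
    logq = -np.log10(np.maximum(t["fdr"].to_numpy(), 1e-300))
    ns = t["call"] == "ns"
    ax.scatter(t.loc[ns, "log2fc"], logq[ns.to_numpy()], s=4, c="lightgrey",
               label="ns")
    for call, color in (("up_A", "tab:red"), ("up_B", "tab:blue")):
        sel = (t["call"] == call).to_numpy()
        label = f"up in {de.group_a}" if call == "up_A" else f"up in {de.group_b}"
        ax.scatter(t["log2fc"].to_numpy()[sel], logq[sel], s=6, c=color, label=label)
    ax.axvline(de.log2fc_cut, color="k", lw=0.6, ls=":")
    ax.axvline(-de.log2fc_cut, color="k", lw=0.6, ls=":")
    ax.axhline(-np.log10(de.fdr_cut), color="k", lw=0.6, ls=":")
    ax.set_xlabel(f"log2 FC ({de.group_a} / {de.group_b})")
    ax.set_ylabel("-log10 FDR")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_contingency(table: ContingencyTable2x2, path=None):
    """Observed counts with expected values in brackets."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.axis("off")
    cells = [
        [f"{int(table.observed[i, j])}\n({table.expected[i, j]:.1f})" for j in range(2)]
        for i in range(2)
    ]
    tab = ax.table(cellText=cells, rowLabels=list(table.row_labels),
                   colLabels=list(table.col_labels), loc="center", cellLoc="center")
    tab.scale(1, 2)
    ax.set_title(
        f"chi-squared = {table.chi_square:.2f}, p = {table.p_value:.2e}", fontsize=9
    )
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
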