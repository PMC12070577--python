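"""Basic diagnostic figures (TSV outputs carry the analysis results)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datatypes import usable_reads


def plot_tail_distributions(records: pd.DataFrame, gene_models, path) -> None:
    """Histograms of mitochondrial vs nuclear tail lengths."""
    reads = usable_reads(records)
    mito_genes = {g for g, m in gene_models.items() if m.is_mitochondrial}
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    for ax, (label, mask) in zip(
        axes,
        [
            ("mitochondrial", reads["gene_id"].isin(mito_genes)),
            ("nuclear", ~reads["gene_id"].isin(mito_genes)),
        ],
    ):
        tails = reads.loc[mask, "polya_length"]
        if len(tails):
            ax.hist(tails, bins=np.arange(0, min(tails.max(), 400) + 5, 5),
                    color="steelblue")
        ax.set_title(f"{label} poly(A) tails")
        ax.set_xlabel("tail length (nt)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_volcano(dp_results: pd.DataFrame, path) -> None:
    """log2FC vs -log10 adjusted p for differential polyadenylation."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    x = dp_results["log2fc"]
    y = -np.log10(dp_results["p_adj"].clip(lower=1e-300))
    colors = np.where(dp_results["is_dpg"], "crimson", "grey")
    ax.scatter(x, y, s=6, c=colors, alpha=0.6, linewidths=0)
    ax.set_xlabel("log2 fold change (viral - bacterial)")
    ax.set_ylabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
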