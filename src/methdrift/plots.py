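"""Minimal summary figures: scree plot and enrichment fold-change bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .decomposition import PcaResult

__all__ = ["scree_plot", "fold_change_plot"]


def scree_plot(pca: PcaResult, path, max_pcs: int = 20) -> None:
    """Bar plot of per-PC variance fractions."""
    frac = pca.variance_fraction[:max_pcs]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(range(1, len(frac) + 1), 100 * frac, color="#4878a8")
    ax.set_xlabel("principal component")
    ax.set_ylabel("% variance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fold_change_plot(frame: pd.DataFrame, path) -> None:
    """Fold-change bars with SE whiskers from an enrichment result frame."""
    sub = frame.dropna(subset=["fold"])
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(sub["feature"], sub["fold"], yerr=sub["fold_se"], capsize=3, color="#a85048")
    ax.axhline(1.0, color="grey", linewidth=0.8, linestyle="--")
    ax.set_ylabel("fold change vs resampled")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
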