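"""Figure helpers: RRHO heat maps, Kaplan-Meier curves, GSEA running sums."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from acidadapt.enrichment import GseaResult
from acidadapt.rrho import RRHOResult
from acidadapt.survival import km_estimate


def rrho_heatmap(result: RRHOResult, path, title: str = "RRHO") -> None:
    """Signed -log10 p map; warm colors mark over-enriched windows."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(result.signed_log_p, origin="lower", cmap="RdYlBu_r", aspect="auto")
    fig.colorbar(im, ax=ax, label="signed -log10 p")
    ax.set_xlabel("patient tumor-vs-normal rank threshold")
    ax.set_ylabel("acid-adaptation rank threshold")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_plot(high: pd.DataFrame, low: pd.DataFrame, path, p_value: float | None = None,
            title: str = "") -> None:
    """Two step curves (high vs low expressors) with an optional p annotation."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for records, label, color in ((high, "high expression", "tab:red"),
                                  (low, "low expression", "tab:blue")):
        curve = km_estimate(records)
        times = np.concatenate([[0.0], curve["time"].to_numpy()])
        surv = np.concatenate([[1.0], curve["survival"].to_numpy()])
        ax.step(times, surv, where="post", label=label, color=color)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if p_value is not None:
        ax.text(0.55, 0.9, f"p = {p_value:.3g}", transform=ax.transAxes)
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def gsea_plot(result: GseaResult, path) -> None:
    """Running enrichment sum with a rug of gene-set hit positions."""
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(5, 3.5), sharex=True, height_ratios=[4, 1]
    )
    ax1.plot(result.running_sum, color="tab:green")
    ax1.axhline(0.0, color="grey", lw=0.6)
    ax1.set_ylabel("enrichment score")
    ax1.set_title(f"{result.set_name}: ES={result.es:.3f}, p={result.perm_p:.3g}")
    ax2.vlines(result.hit_positions, 0, 1, color="black", lw=0.4)
    ax2.set_yticks([])
    ax2.set_xlabel("rank in list")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
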