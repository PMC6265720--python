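"""Figures for the multi-factor rate analysis (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import CellMeans, FACTORS


def rate_distribution_violins(site_table: pd.DataFrame, path: str | Path) -> None:
    """Split rate distributions for the three two-level contrasts."""
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharey=True)
    for ax, (factor, levels) in zip(axes, FACTORS.items()):
        col = f"{factor}_label"
        data = [
            site_table.loc[site_table[col] == lvl, "z_rate"].to_numpy()
            for lvl in levels
        ]
        data = [d for d in data if d.size]
        if data:
            ax.violinplot(data, showmedians=True)
            ax.set_xticks(range(1, len(data) + 1))
            ax.set_xticklabels(levels[: len(data)], fontsize=8)
        ax.set_title(factor)
    axes[0].set_ylabel("z-normalized site rate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def interaction_traces(means: CellMeans, path: str | Path) -> None:
    """Three 2x2 trace plots of cell means (first-order interactions)."""
    pairs = [("disorder", "ss"), ("disorder", "domain"), ("ss", "domain")]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharey=True)
    for ax, (f1, f2) in zip(axes, pairs):
        margin = means.margin(f1, f2)
        for lvl in FACTORS[f2]:
            sub = margin[margin[f2] == lvl]
            order = [lv for lv in FACTORS[f1] if lv in set(sub[f1])]
            ys = [float(sub.loc[sub[f1] == lv, "mean_z"].iloc[0]) for lv in order]
            ax.plot(range(len(order)), ys, marker="o", label=lvl)
        ax.set_xticks(range(len(FACTORS[f1])))
        ax.set_xticklabels(FACTORS[f1], fontsize=8)
        ax.set_title(f"{f1} x {f2}")
        ax.legend(fontsize=7)
    axes[0].set_ylabel("mean z-rate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def loess_scatter(
    disorder_fraction: np.ndarray,
    mean_z: np.ndarray,
    curve: pd.DataFrame,
    path: str | Path,
) -> None:
    """Per-family disordered-structured mean rate vs disorder content."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(disorder_fraction, mean_z, s=12, alpha=0.6)
    ax.plot(curve.disorder_fraction, curve.mean_z, color="C1", lw=2)
    ax.set_xlabel("family disorder content")
    ax.set_ylabel("mean z-rate, disordered-structured sites")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
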