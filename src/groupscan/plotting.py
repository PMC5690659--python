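"""Optional figure exports: RSCU heatmap and binned composition profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_rscu_heatmap", "plot_profiles"]


def plot_rscu_heatmap(rscu_long: pd.DataFrame, path: str | Path,
                      window: str = "middle30") -> None:
    """Codon x group heatmap of RSCU for one positional window."""
    sub = rscu_long[rscu_long.window == window]
    pivot = sub.pivot_table(index="codon", columns="group", values="rscu")
    fig, ax = plt.subplots(figsize=(4 + 0.4 * pivot.shape[1], 12))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=0, vmax=2)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45)
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=6)
    ax.set_title(f"RSCU ({window})")
    fig.colorbar(im, ax=ax, label="RSCU")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profiles(profiles: pd.DataFrame, path: str | Path,
                  metric: str = "gc") -> None:
    """Mean binned 5'->3' profile per group for one metric."""
    sub = profiles[profiles.metric == metric]
    fig, ax = plt.subplots(figsize=(7, 4))
    for group, d in sub.groupby("group"):
        d = d.sort_values("bin")
        ax.plot(d["bin"], d["mean"], label=f"{group} (n={int(d['n'].max())})")
    ax.set_xlabel("relative position bin (5' -> 3')")
    ax.set_ylabel(metric)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
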