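"""Optional matplotlib figures (volcano, heatmap, Venn region barplot)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def volcano(table: pd.DataFrame, path: str | Path, p_max: float = 0.05,
            lfc_min: float = 1.0) -> None:
    t = table.dropna(subset=["p"])
    x = t["log2fc"]
    y = -np.log10(np.clip(t["p"], 1e-300, None))
    sig = t["direction"] != "ns"
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x[~sig], y[~sig], s=4, c="grey", alpha=0.5, linewidths=0)
    ax.scatter(x[sig], y[sig], s=6, c="crimson", linewidths=0)
    ax.axhline(-np.log10(p_max), ls="--", lw=0.6, c="k")
    for v in (-lfc_min, lfc_min):
        ax.axvline(v, ls="--", lw=0.6, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def heatmap(expr: pd.DataFrame, path: str | Path) -> None:
    z = expr.sub(expr.mean(axis=1), axis=0)
    sd = expr.std(axis=1).replace(0, 1.0)
    z = z.div(sd, axis=0)
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(z.shape[1]), z.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def venn_barplot(venn_counts: Mapping[str, int], path: str | Path) -> None:
    keys = sorted(venn_counts)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(range(len(keys)), [venn_counts[k] for k in keys], color="steelblue")
    ax.set_xticks(range(len(keys)), keys, rotation=45, ha="right", fontsize=6)
    ax.set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
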