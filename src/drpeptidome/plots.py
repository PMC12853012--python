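"""Minimal plotting helpers: overlap heatmap and MDS scatter."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .mds import AlleleEmbedding
from .repertoire import OverlapMatrix


def plot_overlap_heatmap(om: OverlapMatrix, path: str | Path) -> None:
    df = om.to_dataframe()
    fig, ax = plt.subplots(figsize=(0.4 * len(df) + 2, 0.4 * len(df) + 2))
    im = ax.imshow(df.values, cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(df)), df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(df)), df.index, fontsize=6)
    fig.colorbar(im, ax=ax, label=f"shared fraction ({om.level})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mds(embeddings: Sequence[AlleleEmbedding], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 6))
    for e in embeddings:
        if e.xy is None:
            continue
        ax.scatter(e.xy[0], e.xy[1], s=20)
        ax.annotate(str(e.unit), e.xy, fontsize=6)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
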