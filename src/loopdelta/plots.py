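"""Headless matplotlib helpers for aggregate-TAD and pile-up grids."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["save_heatmap", "save_pileup"]


def save_heatmap(grid: np.ndarray, path, title: str = "", log2: bool = True) -> None:
    """Write a square grid (aggregate-TAD / O/E map) as a PNG heatmap."""
    data = np.log2(np.where(grid > 0, grid, np.nan)) if log2 else grid
    fig, ax = plt.subplots(figsize=(4, 4))
    vmax = np.nanmax(np.abs(data)) or 1.0
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    fig.colorbar(im, ax=ax, shrink=0.8, label="log2" if log2 else "value")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_pileup(result, path, title: str = "") -> None:
    """Write a PileupResult's mean map with its enrichment annotated."""
    fig, ax = plt.subplots(figsize=(4, 4))
    data = result.mean_map
    im = ax.imshow(data, cmap="coolwarm")
    fig.colorbar(im, ax=ax, shrink=0.8)
    note = []
    if result.central_enrichment is not None:
        note.append(f"central {result.central_enrichment:.2f}")
    if result.stripe_score is not None:
        note.append(f"stripe {result.stripe_score:.2f}")
    ax.set_title(f"{title} ({', '.join(note)}, n={result.n_windows})".strip())
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
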