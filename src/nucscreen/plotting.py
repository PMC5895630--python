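"""Minimal matplotlib output for metaprofiles (aggregate curves, heatmaps)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metaprofile import ProfileMatrix, aggregate_profile


def plot_aggregate_profiles(
    matrices: dict[str, ProfileMatrix], path: str | Path
) -> None:
    """Overlay the aggregate curves of several marks on one axis."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for mark, matrix in matrices.items():
        x = matrix.bin_positions()
        ax.plot(x, aggregate_profile(matrix), label=mark)
    first = next(iter(matrices.values()))
    if first.anchor == "reference_point_TSS":
        ax.axvline(0, color="grey", lw=0.5, ls="--")
        ax.set_xlabel("distance from TSS (bp)")
    else:
        ax.set_xlabel("scaled gene position (bins)")
    ax.set_ylabel("mean coverage")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: ProfileMatrix, path: str | Path, sort: bool = True) -> None:
    """Genes x bins heatmap, optionally sorted by row mean (descending)."""
    values = matrix.values
    if sort and len(values):
        values = values[np.argsort(-values.mean(axis=1))]
    fig, ax = plt.subplots(figsize=(5, 6))
    im = ax.imshow(values, aspect="auto", interpolation="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax, label="coverage")
    ax.set_xlabel("bin")
    ax.set_ylabel("gene")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
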