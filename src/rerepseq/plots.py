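"""Basic figures: feature-centered heatmaps and domain meta-profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_heatmap(matrix: np.ndarray, path: str | Path, title: str = "") -> None:
    """Feature-by-position signal matrix, rows already sorted by signal."""
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(matrix, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_xlabel("position (bins)")
    ax.set_ylabel("features (ranked by signal)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="signal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_meta_profiles(
    profiles: dict[str, np.ndarray], path: str | Path, xlabel: str = "relative position (%)"
) -> None:
    """One trace per condition/time point over a common relative axis."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, meta in profiles.items():
        x = np.linspace(0, 100, len(meta))
        ax.plot(x, meta, label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("mean signal")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
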