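"""Plot helpers (headless backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .embed import Embedding2D
from .metrics import TrajectoryMetrics


def plot_embedding(embedding: Embedding2D, labels: np.ndarray, path) -> None:
    """Scatter of the 2-D embedding coloured by cluster."""
    fig, ax = plt.subplots(figsize=(6, 5), dpi=150)
    labels = np.asarray(labels)
    for c in np.unique(labels):
        sel = labels == c
        ax.scatter(
            embedding.coords[sel, 0],
            embedding.coords[sel, 1],
            s=25,
            label=f"cluster {c}",
        )
    evr = embedding.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%} var)")
    ax.set_ylabel(f"PC2 ({evr[1]:.0%} var)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_trajectories(tm: TrajectoryMetrics, path, column="avg_degree_centrality") -> None:
    """Line plot with one per-cluster series over the timepoints."""
    fig, ax = plt.subplots(figsize=(7, 4.5), dpi=150)
    order = list(dict.fromkeys(tm.frame["timepoint"]))
    for c in sorted(tm.frame["cluster"].unique()):
        sub = tm.frame[tm.frame["cluster"] == c].set_index("timepoint").loc[order]
        ax.plot(order, sub[column], marker="o", label=f"cluster {c}")
    ax.set_xlabel("timepoint")
    ax.set_ylabel(column.replace("_", " "))
    ax.set_title(f"mode={tm.mode}, r_min={tm.r_min}")
    ax.legend()
    ax.grid(True, alpha=0.4)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
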