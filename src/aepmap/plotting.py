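"""Probability-map rendering."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classifiers import ProbabilityGrid


def plot_probability_map(
    grid: ProbabilityGrid,
    points_X: np.ndarray | None = None,
    points_y=None,
    title: str = "",
    path=None,
):
    """Render p(good | x) over the normalized map, optionally with the cohort.

    Good-outcome patients are drawn in red, bad-outcome in blue, over the
    posterior surface with the p = 0.5 decision contour.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(
        grid.x_coords, grid.y_coords, grid.values, cmap="RdBu_r",
        vmin=0.0, vmax=1.0, shading="nearest",
    )
    ax.contour(grid.x_coords, grid.y_coords, grid.values, levels=[0.5],
               colors="k", linewidths=0.8)
    if points_X is not None:
        points_X = np.asarray(points_X)
        labels = np.asarray(points_y) if points_y is not None else np.array(
            ["unknown"] * len(points_X)
        )
        for label, color, marker in (("good", "red", "o"), ("bad", "blue", "s"),
                                     ("unknown", "gray", "x")):
            sel = labels == label
            if sel.any():
                ax.scatter(points_X[sel, 0], points_X[sel, 1], c=color,
                           marker=marker, edgecolors="k", linewidths=0.4,
                           s=35, label=label, zorder=3)
        ax.legend(loc="best", fontsize=8)
    fig.colorbar(im, ax=ax, label="p(good outcome)")
    ax.set_xlabel("normalized feature 1")
    ax.set_ylabel("normalized feature 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
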