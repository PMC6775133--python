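"""Topographic maps over electrode-grid coordinates.

Winner-takes-all maps label each electrode with the movement that has the
highest r², keeping only electrodes whose best r² exceeds an inclusion
threshold (default 0.2).  Mean-r² maps arrange the per-class r² values on
the (row, col) grid for rendering.  Maps live in electrode-grid
coordinates; no cortical-surface normalization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .select import SelectionResult
from .sim import GridLayout

__all__ = ["TopoMap", "winner_takes_all", "mean_r2_map", "topomap_to_frame",
           "plot_topomap"]


@dataclass(frozen=True)
class TopoMap:
    """Per-electrode winning movement and r² grids."""

    winner: np.ndarray      # (R, C) int index into movements; -1 = below threshold
    winner_r2: np.ndarray   # (R, C) max r² over movements
    r2_grids: np.ndarray    # (n_movements, R, C)
    movements: tuple[str, ...]
    threshold: float
    layout: GridLayout


def mean_r2_map(selection: SelectionResult, layout: GridLayout) -> np.ndarray:
    """Per-class r² values arranged on the (row, col) grid, unchanged."""
    n_m = len(selection.movements)
    if selection.r2.shape[0] != layout.n_channels:
        raise ValueError("selection covers a different electrode count than layout")
    return selection.r2.T.reshape(n_m, layout.n_rows, layout.n_cols)


def winner_takes_all(selection: SelectionResult, layout: GridLayout,
                     threshold: float = 0.2) -> TopoMap:
    """Label each electrode with the movement of its highest r².

    Electrodes whose best r² is not strictly above ``threshold`` get no
    winner (-1).  Ties go to the lowest movement index.
    """
    grids = mean_r2_map(selection, layout)
    best = grids.max(axis=0)
    winner = grids.argmax(axis=0).astype(np.int64)
    winner[best <= threshold] = -1
    return TopoMap(winner, best, grids, selection.movements, threshold, layout)


def topomap_to_frame(tm: TopoMap) -> pd.DataFrame:
    """Long-format (row, col, class, r2, winner) table for TSV export."""
    rows = []
    for r in range(tm.layout.n_rows):
        for c in range(tm.layout.n_cols):
            win = tm.movements[tm.winner[r, c]] if tm.winner[r, c] >= 0 else "none"
            for m, mov in enumerate(tm.movements):
                rows.append((r, c, mov, round(float(tm.r2_grids[m, r, c]), 6), win))
    return pd.DataFrame(rows, columns=["row", "col", "class", "r2", "winner"])


def plot_topomap(tm: TopoMap, path=None):
    """Heatmaps: one panel per movement (r²) plus the winner-takes-all map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_m = len(tm.movements)
    fig, axes = plt.subplots(1, n_m + 1, figsize=(3 * (n_m + 1), 3))
    for m, mov in enumerate(tm.movements):
        ax = axes[m]
        im = ax.imshow(tm.r2_grids[m], vmin=0, vmax=max(1e-9, tm.r2_grids.max()),
                       cmap="viridis")
        ax.set_title(f"r²: {mov}")
        fig.colorbar(im, ax=ax, shrink=0.7)
    ax = axes[-1]
    masked = np.ma.masked_where(tm.winner < 0, tm.winner)
    im = ax.imshow(masked, cmap="tab10", vmin=0, vmax=max(9, n_m - 1))
    ax.set_title(f"winner (r² > {tm.threshold:g})")
    for a in axes:
        a.set_xlabel("col")
        a.set_ylabel("row")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
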