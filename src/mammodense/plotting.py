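"""Plots of regional percent density and segmentation overlays."""

from __future__ import annotations

import numpy as np

from .regional import ZONES, RegionalGrid, default_zone_map

ZONE_COLORS = {"posterior": "tab:green", "middle": "tab:blue", "anterior": "tab:red"}


def plot_regional_grid(grid: RegionalGrid, zone_map=None, ax=None, annotate=True):
    """Heatmap of the 6x8 regional-PD matrix with zone-colored cell borders.

    Chest wall (posterior, column 1) is on the left, nipple side on the
    right; the numeric annotation in each cell is its regional PD in %.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 6))
    if zone_map is None:
        zone_map = default_zone_map(grid.ncols, grid.nrows)
    shown = np.where(grid.empty, np.nan, grid.regional_pd)
    im = ax.imshow(shown, cmap="magma", vmin=0, vmax=100, aspect="auto")
    for (c, r), zone in zone_map.items():
        ax.add_patch(Rectangle((c - 1.5, r - 1.5), 1, 1, fill=False,
                               edgecolor=ZONE_COLORS[zone], linewidth=1.5))
        if annotate and not grid.empty[r - 1, c - 1]:
            ax.text(c - 1, r - 1, f"{grid.regional_pd[r - 1, c - 1]:.0f}",
                    ha="center", va="center", fontsize=8,
                    color="white" if grid.regional_pd[r - 1, c - 1] < 60 else "black")
    ax.set_xticks(range(grid.ncols), [str(c) for c in range(1, grid.ncols + 1)])
    ax.set_yticks(range(grid.nrows), [str(r) for r in range(1, grid.nrows + 1)])
    ax.set_xlabel("column (1 = chest wall)")
    ax.set_ylabel("row")
    plt.colorbar(im, ax=ax, label="regional PD (%)")
    return ax


def plot_segmentation(pixels: np.ndarray, dense_map: np.ndarray, ax=None):
    """Mammogram with the segmented dense tissue shown as a white overlay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(pixels, cmap="gray", vmin=0, vmax=255)
    overlay = np.zeros((*dense_map.shape, 4))
    overlay[dense_map] = (1.0, 1.0, 1.0, 0.85)
    ax.imshow(overlay)
    ax.set_axis_off()
    return ax
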