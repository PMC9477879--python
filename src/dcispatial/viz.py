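"""Plotting of typed Voronoi partitions over duct masks.

Colours follow the convention used for component maps of mixed sections:
synchronous-DCIS polygons red, IDC polygons green, mixed polygons orange,
excluded polygons gray; duct outlines are shaded yellow underneath.
"""

from __future__ import annotations

from .cells import DuctMask
from .regions import RegionPartition

REGION_COLORS = {
    "synchronous_DCIS": "#d62728",
    "IDC": "#2ca02c",
    "mixed": "#ff7f0e",
    "excluded": "#bbbbbb",
    None: "#1f77b4",
}


def plot_partition(
    partition: RegionPartition,
    ducts: DuctMask | None = None,
    ax=None,
    alpha: float = 0.45,
):
    """Draw the typed partition; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    if ducts is not None:
        for poly in ducts.polygons:
            xs, ys = poly.exterior.xy
            ax.fill(xs, ys, color="#ffdf00", alpha=0.6, lw=0)
    for poly in partition.polygons:
        color = REGION_COLORS.get(poly.region_type, "#1f77b4")
        xs, ys = poly.geometry.exterior.xy
        ax.fill(xs, ys, facecolor=color, alpha=alpha, edgecolor="black", lw=0.5)
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention, y down
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    return ax
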