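"""Heatmap rendering of per-cell scores over cell polygons.

Color limits are fixed per metric ([0, 45] for LMS, [0, 90] for GOA) rather
than data-driven, so heatmaps of different samples and genotypes are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import PolyCollection

from .geometry import Cell

__all__ = ["HeatmapSpec", "render_heatmap"]

_METRIC_COLUMN = {"lms": "lms_deg", "goa": "goa_deg"}
_METRIC_LIMITS = {"lms": (0.0, 45.0), "goa": (0.0, 90.0)}


@dataclass
class HeatmapSpec:
    """Rendering parameters for a score heatmap.

    ``metric`` selects the score and fixes the color-scale limits; cells with
    undefined scores are drawn in ``undefined_color``. ``background`` may be
    a 2-D greyscale array (e.g. a DAPI raster) with an extent in μm.
    """

    metric: str = "lms"
    cmap: str = "viridis"
    undefined_color: str = "#bbbbbb"
    background: np.ndarray | None = None
    background_extent: tuple[float, float, float, float] | None = None
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.metric not in _METRIC_LIMITS:
            raise ValueError(f"metric must be one of {sorted(_METRIC_LIMITS)}")

    @property
    def limits(self) -> tuple[float, float]:
        return _METRIC_LIMITS[self.metric]


def render_heatmap(
    cells: list[Cell],
    scores: pd.DataFrame,
    spec: HeatmapSpec,
    path: str | Path,
) -> None:
    """Fill each cell polygon with its metric value on the fixed color scale.

    Deterministic for fixed inputs; a colorbar with the metric's full range
    and a 100 μm scale bar are embedded. Raises if the metric column is
    absent or defined for no cell.
    """
    column = _METRIC_COLUMN[spec.metric]
    if column not in scores.columns:
        raise ValueError(f"score table has no {column!r} column")
    values = scores[column].reindex([c.id for c in cells])
    if not values.notna().any():
        raise ValueError(f"{column!r} is undefined for every cell")
    vmin, vmax = spec.limits

    fig, ax = plt.subplots(figsize=(8, 8), dpi=spec.dpi)
    if spec.background is not None:
        ax.imshow(
            spec.background,
            cmap="gray",
            extent=spec.background_extent,
            origin="upper",
        )
    verts = [np.asarray(c.polygon.exterior.coords) for c in cells]
    vals = values.to_numpy(dtype=float)
    defined = np.isfinite(vals)
    cmap = plt.get_cmap(spec.cmap)
    norm = plt.Normalize(vmin=vmin, vmax=vmax)
    facecolors = np.empty((len(cells), 4))
    facecolors[defined] = cmap(norm(vals[defined]))
    facecolors[~defined] = matplotlib.colors.to_rgba(spec.undefined_color)
    ax.add_collection(
        PolyCollection(verts, facecolors=facecolors, edgecolors="none")
    )
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image frame: y grows downward
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, label=f"{spec.metric.upper()} (deg)", shrink=0.8)
    # 100 μm scale bar in the lower-left corner
    x0, x1 = ax.get_xlim()
    ylo, yhi = ax.get_ylim()
    bx = x0 + 0.05 * (x1 - x0)
    by = ylo + 0.05 * (yhi - ylo)
    ax.plot([bx, bx + 100.0], [by, by], color="black", lw=3)
    ax.annotate("100 μm", (bx, by), textcoords="offset points", xytext=(0, 5))
    fig.savefig(path, metadata={"Software": None} if str(path).endswith(".png") else None)
    plt.close(fig)
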