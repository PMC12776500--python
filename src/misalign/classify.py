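"""Sequential cell-type classification, HZ-distance zoning and filtering.

Cells are classified by centroid membership in marker-positive regions with
a fixed precedence: chondro-hyper (Col2+ and ColX+), else chondrocyte
(Col2+), else myocyte (Muscle+), else other. Chondrocytes within a distance
window of the hypertrophic zone (HZ) — the proliferative-zone proxy,
0–400 μm by default — are then relabeled chondro-PZ. Distances are
straight-line (Euclidean) from the cell centroid to the nearest point of
any HZ polygon, zero inside the HZ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point
from shapely.ops import unary_union

from .geometry import Cell, RegionSet

__all__ = [
    "CLASS_LABELS",
    "DistanceProfile",
    "classify_by_regions",
    "distance_to_hz",
    "assign_pz",
    "bin_by_distance",
    "filter_cells",
]

CLASS_LABELS = ("chondrocyte", "chondro-hyper", "myocyte", "chondro-PZ", "other")

#: Default chondro-PZ window: chondrocytes adjacent to the HZ, [0, 400) μm.
DEFAULT_PZ_WINDOW = (0.0, 400.0)


@dataclass
class DistanceProfile:
    """Score aggregates over half-open distance bins ``[k·w, (k+1)·w)``."""

    bin_edges: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_um": self.bin_edges[:-1],
                "bin_hi_um": self.bin_edges[1:],
                "mean": self.mean,
                "median": self.median,
                "count": self.count,
            }
        )


def _membership(cells: list[Cell], polygons) -> np.ndarray:
    """Boolean centroid-in-region mask (boundary inclusive)."""
    out = np.zeros(len(cells), dtype=bool)
    if not polygons:
        return out
    tree = STRtree(polygons)
    for k, cell in enumerate(cells):
        out[k] = len(tree.query(Point(cell.centroid), predicate="intersects")) > 0
    return out


def classify_by_regions(cells: list[Cell], regions: RegionSet) -> list[Cell]:
    """Assign class labels by sequential marker-region membership (in place).

    Precedence: centroid in Col2 ∩ ColX → chondro-hyper; else in Col2 →
    chondrocyte; else in a muscle region → myocyte; else other. Raises if the
    required Col2/ColX/muscle roles are all absent.
    """
    col2 = regions.by_role("marker:Col2")
    colx = regions.by_role("marker:ColX")
    muscle = regions.by_role("muscle")
    if not col2 and not colx and not muscle:
        raise ValueError(
            "regions must include at least one of marker:Col2, marker:ColX, muscle"
        )
    in_col2 = _membership(cells, col2)
    in_colx = _membership(cells, colx)
    in_muscle = _membership(cells, muscle)
    for k, cell in enumerate(cells):
        if in_col2[k] and in_colx[k]:
            cell.class_label = "chondro-hyper"
        elif in_col2[k]:
            cell.class_label = "chondrocyte"
        elif in_muscle[k]:
            cell.class_label = "myocyte"
        else:
            cell.class_label = "other"
    return cells


def distance_to_hz(cells: list[Cell], regions: RegionSet) -> pd.Series:
    """Euclidean distance (μm) from each centroid to the nearest HZ polygon.

    Zero for centroids inside the HZ. Raises if no region carries the ``hz``
    role.
    """
    hz_polys = regions.by_role("hz")
    if not hz_polys:
        raise ValueError("no region with role 'hz'")
    hz = unary_union(hz_polys)
    out = {c.id: float(hz.distance(Point(c.centroid))) for c in cells}
    return pd.Series(out, name="distance_to_hz_um", dtype=float)


def assign_pz(
    cells: list[Cell],
    distances: pd.Series,
    window: tuple[float, float] = DEFAULT_PZ_WINDOW,
) -> list[Cell]:
    """Relabel chondrocytes within the half-open HZ-distance window as chondro-PZ.

    Only cells currently labeled ``chondrocyte`` are touched; chondro-hyper
    cells are never relabeled. Idempotent.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError(f"window must satisfy lo < hi, got {window}")
    for cell in cells:
        if cell.class_label == "chondrocyte":
            d = distances.get(cell.id)
            if d is not None and lo <= d < hi:
                cell.class_label = "chondro-PZ"
    return cells


def bin_by_distance(
    scores: pd.Series, distances: pd.Series, bin_width: float
) -> DistanceProfile:
    """Aggregate a per-cell score into half-open distance bins of fixed width.

    Undefined (NaN) scores are dropped before binning. Empty bins report
    count 0 and NaN aggregates.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    joined = pd.DataFrame({"score": scores, "d": distances}).dropna()
    if joined.empty:
        raise ValueError("no defined scores to bin")
    n_bins = int(np.floor(joined["d"].max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    which = np.floor(joined["d"].to_numpy() / bin_width).astype(int)
    mean = np.full(n_bins, np.nan)
    median = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    vals = joined["score"].to_numpy()
    for b in range(n_bins):
        sel = vals[which == b]
        count[b] = sel.size
        if sel.size:
            mean[b] = sel.mean()
            median[b] = np.median(sel)
    return DistanceProfile(bin_edges=edges, mean=mean, median=median, count=count)


def filter_cells(
    cells: list[Cell],
    cartilage_region=None,
    edge_margin: float = 0.0,
    min_area: float = 0.0,
    max_area: float = np.inf,
) -> tuple[list[Cell], dict[str, int]]:
    """Drop edge-located and out-of-size cells.

    A cell is an edge cell when its centroid lies within ``edge_margin`` μm
    of the cartilage-region boundary; size filtering drops cells with area
    outside ``[min_area, max_area]`` μm². Returns the kept subset and
    exclusion counts keyed by reason (a cell failing both counts once, as
    ``edge``).
    """
    if edge_margin < 0:
        raise ValueError("edge_margin must be >= 0")
    if min_area > max_area:
        raise ValueError("min_area must not exceed max_area")
    boundary = None
    if cartilage_region is not None and edge_margin > 0:
        if isinstance(cartilage_region, RegionSet):
            polys = cartilage_region.by_role("cartilage")
            boundary = unary_union(polys).boundary if polys else None
        else:
            boundary = cartilage_region.boundary
    kept: list[Cell] = []
    dropped = {"edge": 0, "size": 0}
    for cell in cells:
        if boundary is not None and boundary.distance(Point(cell.centroid)) < edge_margin:
            dropped["edge"] += 1
            continue
        if not (min_area <= cell.area <= max_area):
            dropped["size"] += 1
            continue
        kept.append(cell)
    return kept, dropped
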