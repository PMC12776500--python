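"""Nucleus-to-cell matching for compartmental measurements.

Nuclei segmented separately from cell bodies are paired to cells by centroid
containment followed by nearest-centroid distance (kd-tree); nuclei whose
centroid falls inside no cell polygon are excluded from analysis.
"""

from __future__ import annotations

import logging

import numpy as np
from shapely import STRtree
from shapely.geometry import Point

from .geometry import Cell

logger = logging.getLogger(__name__)

__all__ = ["pair_nuclei_to_cells"]


def pair_nuclei_to_cells(
    nuclei: list[Cell], cells: list[Cell]
) -> tuple[list[tuple[str, str]], int]:
    """Pair each nucleus with its containing cell, nearest centroid first.

    A nucleus whose centroid lies in one or more cell polygons is paired
    with the candidate whose centroid is nearest (ties broken by lowest cell
    id). Nuclei contained in no cell are excluded. Returns the pair list and
    the exclusion count.
    """
    if not cells:
        raise ValueError("empty cell list")
    if not nuclei:
        raise ValueError("empty nucleus list")
    tree = STRtree([c.polygon for c in cells])
    centroids = np.array([c.centroid for c in cells])
    pairs: list[tuple[str, str]] = []
    excluded = 0
    for nucleus in nuclei:
        pt = Point(nucleus.centroid)
        candidates = [
            int(i) for i in tree.query(pt, predicate="intersects")
        ]  # boundary counts as containment
        if not candidates:
            excluded += 1
            continue
        d = np.hypot(
            centroids[candidates, 0] - nucleus.centroid[0],
            centroids[candidates, 1] - nucleus.centroid[1],
        )
        dmin = d.min()
        best = min(cells[i].id for i, di in zip(candidates, d) if di <= dmin + 1e-12)
        pairs.append((nucleus.id, best))
    if excluded:
        logger.info("excluded %d nuclei contained in no cell polygon", excluded)
    return pairs, excluded
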