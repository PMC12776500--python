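"""Reading and writing segmented cells, annotations and score tables.

Cells arrive either as QuPath-dialect GeoJSON feature collections (polygon
features whose ``properties`` may carry ``classification``, ``measurements``
and a parent-annotation id) or as integer label-mask TIFFs. Coordinates in
files are pixels; everything is converted to μm at read time using a
:class:`~misalign.geometry.PixelCalibration`, so that all downstream radii
and thresholds are physical distances.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import uniform_filter1d
from shapely.geometry import Polygon, shape
from shapely.affinity import scale as shapely_scale
from skimage import measure

from .geometry import Cell, DegenerateGeometryError, PixelCalibration, RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_cells_geojson",
    "write_cells_geojson",
    "read_cells_labelmask",
    "read_regions_geojson",
    "write_regions_geojson",
    "write_score_table",
    "read_score_table",
]


class EmptyInputError(ValueError):
    """File parsed fine but contained no usable objects."""


def _to_microns(polygon: Polygon, calibration: PixelCalibration) -> Polygon:
    s = calibration.microns_per_pixel
    return shapely_scale(polygon, xfact=s, yfact=s, origin=(0, 0))


def _feature_polygon(feature: dict) -> Polygon | None:
    geom = feature.get("geometry")
    if geom is None or geom.get("type") not in ("Polygon", "MultiPolygon"):
        return None
    g = shape(geom)
    if g.geom_type == "MultiPolygon":
        g = max(g.geoms, key=lambda p: p.area)
    ring = list(g.exterior.coords)
    if len(ring) - 1 < 3:  # closed ring repeats the first vertex
        return None
    return g


def _feature_properties(feature: dict) -> tuple[dict[str, float], str | None, str | None]:
    """Extract (markers, class_label, annotation_id) from QuPath-ish properties."""
    props = feature.get("properties") or {}
    markers: dict[str, float] = {}
    meas = props.get("measurements")
    if isinstance(meas, dict):
        markers = {str(k): float(v) for k, v in meas.items()}
    elif isinstance(meas, list):  # older QuPath exports: [{"name":..., "value":...}]
        markers = {str(m["name"]): float(m["value"]) for m in meas if "name" in m}
    cls = props.get("classification")
    if isinstance(cls, dict):
        label = cls.get("name")
    else:
        label = cls if isinstance(cls, str) else None
    annotation_id = props.get("annotation_id") or props.get("parent")
    return markers, label, annotation_id


def read_cells_geojson(path: str | Path, calibration: PixelCalibration) -> list[Cell]:
    """Read segmented cells from a GeoJSON feature collection (pixel coords).

    Each polygonal feature becomes one :class:`Cell` with μm coordinates.
    Marker measurements and classification strings are carried through when
    present; features with fewer than 3 distinct vertices are skipped with a
    warning. Raises :class:`EmptyInputError` if no polygonal feature remains.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    features = doc.get("features", [])
    cells: list[Cell] = []
    skipped = 0
    for k, feature in enumerate(features):
        poly = _feature_polygon(feature)
        if poly is None:
            skipped += 1
            continue
        markers, label, annotation_id = _feature_properties(feature)
        props = feature.get("properties") or {}
        cell_id = str(feature.get("id") or props.get("id") or f"{path.stem}:{k}")
        compartment = props.get("compartment", "cell")
        try:
            cells.append(
                Cell.from_polygon(
                    cell_id,
                    _to_microns(poly, calibration),
                    annotation_id=annotation_id,
                    markers=markers,
                    compartment=compartment,
                    class_label=label,
                )
            )
        except DegenerateGeometryError:
            skipped += 1
    if skipped:
        logger.warning("%s: skipped %d degenerate/non-polygonal features", path, skipped)
    if not cells:
        raise EmptyInputError(f"{path}: no polygonal features")
    return cells


def write_cells_geojson(
    cells: list[Cell],
    path: str | Path,
    calibration: PixelCalibration,
    *,
    extra_properties: dict[str, dict] | None = None,
) -> None:
    """Write cells as a QuPath-dialect feature collection in pixel coordinates."""
    s = calibration.microns_per_pixel
    features = []
    for cell in cells:
        ring = [[x / s, y / s] for x, y in cell.polygon.exterior.coords]
        props: dict = {"objectType": "detection", "compartment": cell.compartment}
        if cell.class_label is not None:
            props["classification"] = {"name": cell.class_label}
        if cell.markers:
            props["measurements"] = cell.markers
        if cell.annotation_id is not None:
            props["annotation_id"] = cell.annotation_id
        if extra_properties and cell.id in extra_properties:
            props.update(extra_properties[cell.id])
        features.append(
            {
                "type": "Feature",
                "id": cell.id,
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_cells_labelmask(path: str | Path, calibration: PixelCalibration) -> list[Cell]:
    """Read cells from an integer label-mask image (0 = background).

    Each positive label yields one cell whose polygon is the traced outer
    contour of the label's largest connected component (smaller fragments are
    dropped with a warning).
    """
    path = Path(path)
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D label image, got shape {img.shape}")
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError(f"{path}: label mask must be integer-valued, got {img.dtype}")
    labels = np.unique(img)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise EmptyInputError(f"{path}: all-background label mask")
    cells: list[Cell] = []
    split_labels = 0
    for lab in labels:
        mask = img == lab
        cc = measure.label(mask, connectivity=2)
        if cc.max() > 1:
            split_labels += 1
            sizes = np.bincount(cc.ravel())[1:]
            mask = cc == (int(np.argmax(sizes)) + 1)
        contours = measure.find_contours(np.pad(mask, 1).astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        # circular moving average suppresses the pixel staircase, which
        # otherwise perturbs the max-Feret chord by several degrees
        window = min(7, max(1, len(contour) // 4))
        contour = np.column_stack(
            [
                uniform_filter1d(contour[:, 0], window, mode="wrap"),
                uniform_filter1d(contour[:, 1], window, mode="wrap"),
            ]
        )
        # find_contours returns (row, col) pixel indices on the padded grid;
        # shift off the pad, move to pixel centers (+0.5) and swap to (x, y)
        xy = np.column_stack([contour[:, 1] - 0.5, contour[:, 0] - 0.5])
        try:
            poly = Polygon(xy)
            cells.append(
                Cell.from_polygon(str(int(lab)), _to_microns(poly, calibration))
            )
        except (DegenerateGeometryError, ValueError):
            logger.warning("%s: label %d has degenerate contour, skipped", path, lab)
    if split_labels:
        logger.warning(
            "%s: %d labels split into multiple components; kept largest each",
            path,
            split_labels,
        )
    if not cells:
        raise EmptyInputError(f"{path}: no traceable labels")
    return cells


def read_regions_geojson(path: str | Path, calibration: PixelCalibration) -> RegionSet:
    """Read annotation polygons with role tags from GeoJSON.

    Each feature's ``properties.role`` must be one of the closed vocabulary
    (``cartilage | hz | muscle | marker:<name> | element:<n>``); the region
    name comes from ``properties.name`` (default: role plus index).
    """
    with open(path) as fh:
        doc = json.load(fh)
    regions = RegionSet()
    grouped: dict[tuple[str, str], list[Polygon]] = {}
    for k, feature in enumerate(doc.get("features", [])):
        poly = _feature_polygon(feature)
        if poly is None:
            continue
        props = feature.get("properties") or {}
        role = props.get("role")
        if role is None:
            raise ValueError(f"{path}: feature {k} has no 'role' property")
        name = props.get("name", f"{role}-{k}")
        grouped.setdefault((name, role), []).append(_to_microns(poly, calibration))
    for (name, role), polys in grouped.items():
        regions.add(name, polys, role)
    return regions


def write_regions_geojson(
    regions: RegionSet, path: str | Path, calibration: PixelCalibration
) -> None:
    s = calibration.microns_per_pixel
    features = []
    for name, polys in regions.regions.items():
        for poly in polys:
            ring = [[x / s, y / s] for x, y in poly.exterior.coords]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "objectType": "annotation",
                        "name": name,
                        "role": regions.roles[name],
                    },
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


SCORE_COLUMNS = [
    "id",
    "annotation_id",
    "centroid_x_um",
    "centroid_y_um",
    "orientation_deg",
    "class_label",
    "goa_deg",
    "lms_deg",
    "neighbor_count",
    "distance_to_hz_um",
]


def write_score_table(cells: list[Cell], scores: pd.DataFrame, path: str | Path) -> None:
    """Write one CSV row per cell, ordered by id, undefined scores as empty fields.

    ``scores`` is indexed by cell id and may provide any of ``goa_deg``,
    ``lms_deg``, ``raw_mean_diff_deg``, ``neighbor_count``,
    ``distance_to_hz_um``. Raises on ids present in ``scores`` but not among
    the cells.
    """
    cell_ids = {c.id for c in cells}
    extra = set(scores.index.astype(str)) - cell_ids
    if extra:
        raise ValueError(f"score table has {len(extra)} ids not among cells")
    rows = []
    for cell in sorted(cells, key=lambda c: c.id):
        row = {
            "id": cell.id,
            "annotation_id": cell.annotation_id,
            "centroid_x_um": cell.centroid[0],
            "centroid_y_um": cell.centroid[1],
            "orientation_deg": cell.orientation_deg,
            "class_label": cell.class_label,
        }
        if cell.id in scores.index:
            for col in ("goa_deg", "lms_deg", "raw_mean_diff_deg",
                        "neighbor_count", "distance_to_hz_um"):
                if col in scores.columns:
                    row[col] = scores.loc[cell.id, col]
        rows.append(row)
    df = pd.DataFrame(rows)
    if "neighbor_count" in df.columns:
        df["neighbor_count"] = df["neighbor_count"].astype("Int64")
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
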