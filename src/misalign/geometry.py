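"""Cell and region geometry primitives.

Angle convention used throughout the package: orientations are axial
(180°-periodic) angles in degrees in ``[0, 180)``, measured counterclockwise
from the +x image axis with y increasing downward, exactly as coordinates are
stored in the image. Any consistent frame works because every score is an
angular difference. Coordinates are in micrometres once a file is read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

#: Aspect ratio (max Feret / min Feret) below which an orientation is
#: considered unreliable for a near-round cell.
LOW_ANISOTROPY_RATIO = 1.1

# Region role vocabulary (closed).
REGION_ROLES = ("cartilage", "hz", "muscle")  # plus "marker:<name>", "element:<0..5>"


class DegenerateGeometryError(ValueError):
    """Polygon has no usable extent (zero area / collinear vertices)."""


@dataclass
class PixelCalibration:
    """Physical pixel size of the source image.

    Parameters
    ----------
    microns_per_pixel : float
        Strictly positive μm/px scale applied at read time.
    """

    microns_per_pixel: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.microns_per_pixel) and self.microns_per_pixel > 0):
            raise ValueError(
                f"microns_per_pixel must be finite and > 0, got {self.microns_per_pixel!r}"
            )


@dataclass
class Cell:
    """A segmented cell (or nucleus) with derived geometry in μm.

    ``orientation_deg`` is the axial major-axis (max Feret diameter) angle in
    ``[0, 180)``. ``low_anisotropy`` flags near-round cells whose orientation
    is numerically defined but biologically unreliable.
    """

    id: str
    polygon: Polygon
    centroid: tuple[float, float]
    area: float
    orientation_deg: float
    annotation_id: str | None = None
    markers: dict[str, float] = field(default_factory=dict)
    compartment: str = "cell"  # "cell" | "nucleus"
    class_label: str | None = None
    low_anisotropy: bool = False

    @classmethod
    def from_polygon(
        cls,
        id: str,
        polygon: Polygon,
        *,
        annotation_id: str | None = None,
        markers: dict[str, float] | None = None,
        compartment: str = "cell",
        class_label: str | None = None,
    ) -> "Cell":
        """Build a cell from a shapely polygon already in μm."""
        polygon = repair_polygon(polygon)
        angle, low = orientation_from_polygon(polygon, return_flag=True)
        c = polygon.centroid
        return cls(
            id=id,
            polygon=polygon,
            centroid=(c.x, c.y),
            area=polygon.area,
            orientation_deg=angle,
            annotation_id=annotation_id,
            markers=dict(markers or {}),
            compartment=compartment,
            class_label=class_label,
            low_anisotropy=low,
        )


@dataclass
class RegionSet:
    """Named annotation polygons with role tags.

    ``roles`` maps region name → one of ``cartilage | hz | muscle |
    marker:<name> | element:<0..5>``.
    """

    regions: dict[str, list[Polygon]] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, polygons: list[Polygon] | Polygon, role: str) -> None:
        if isinstance(polygons, Polygon):
            polygons = [polygons]
        if not _valid_role(role):
            raise ValueError(f"unknown region role {role!r}")
        self.regions[name] = [repair_polygon(p) for p in polygons]
        self.roles[name] = role

    def by_role(self, role: str) -> list[Polygon]:
        """All polygons whose region carries exactly this role tag."""
        out: list[Polygon] = []
        for name, r in self.roles.items():
            if r == role:
                out.extend(self.regions[name])
        return out


def _valid_role(role: str) -> bool:
    if role in REGION_ROLES:
        return True
    if role.startswith("marker:") and len(role) > len("marker:"):
        return True
    if role.startswith("element:"):
        suffix = role.split(":", 1)[1]
        return suffix in {"0", "1", "2", "3", "4", "5"}
    return False


def repair_polygon(polygon: Polygon) -> Polygon:
    """Repair self-intersections by the zero-buffer convention.

    Raises :class:`DegenerateGeometryError` if the result has no area.
    """
    if not polygon.is_valid:
        polygon = polygon.buffer(0)
        if polygon.geom_type == "MultiPolygon":
            polygon = max(polygon.geoms, key=lambda g: g.area)
    if polygon.is_empty or polygon.area <= 0:
        raise DegenerateGeometryError("polygon has zero area after repair")
    return polygon


def _hull_points(polygon: Polygon) -> np.ndarray:
    hull = polygon.convex_hull
    if hull.geom_type != "Polygon":
        raise DegenerateGeometryError("degenerate polygon: convex hull is not areal")
    return np.asarray(hull.exterior.coords)[:-1]


def _max_feret_info(polygon: Polygon) -> tuple[float, float, bool]:
    """(diameter, axial angle, symmetric_tie) of the longest hull chord."""
    pts = _hull_points(polygon)
    n = len(pts)
    if n < 3:
        raise DegenerateGeometryError("fewer than 3 hull vertices")
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    dmax2 = d2.max()
    if dmax2 <= 0:
        raise DegenerateGeometryError("all vertices coincide")
    ii, jj = np.where(d2 >= dmax2 * (1.0 - 1e-9))
    keep = ii < jj
    vecs = diff[ii[keep], jj[keep]]
    angles = np.degrees(np.arctan2(vecs[:, 1], vecs[:, 0])) % 180.0
    symmetric_tie = False
    if len(angles) == 1:
        angle = float(angles[0])
    else:
        # axial mean of tied chords: double, average unit vectors, halve
        doubled = np.radians(2.0 * angles)
        sx, sy = np.cos(doubled).sum(), np.sin(doubled).sum()
        if math.hypot(sx, sy) < 1e-9 * len(angles):
            # fully symmetric tie (e.g. the diagonals of a square): no
            # preferred direction; break to the smallest qualifying angle
            symmetric_tie = True
            angle = float(np.min(angles))
        else:
            angle = math.degrees(math.atan2(sy, sx)) / 2.0 % 180.0
    return float(np.sqrt(dmax2)), angle % 180.0, symmetric_tie


def max_feret(polygon: Polygon) -> tuple[float, float]:
    """Maximum Feret (caliper) diameter of the convex hull and its angle.

    Returns ``(diameter, angle_deg)`` with the angle axial in ``[0, 180)``.
    Ties between equally long chords (e.g. the two diagonals of a
    rectangle) are combined by their axial mean; a fully symmetric tie whose
    axial resultant vanishes falls back to the smallest qualifying angle.
    """
    d, angle, _ = _max_feret_info(polygon)
    return d, angle


def min_feret(polygon: Polygon) -> float:
    """Minimum caliper width of the convex hull (rotating-calipers contract)."""
    pts = _hull_points(polygon)
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    ok = lengths > 0
    normals = np.stack([-edges[ok, 1], edges[ok, 0]], axis=1) / lengths[ok, None]
    # width along each edge normal = spread of vertex projections
    proj = pts @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())


def orientation_from_polygon(
    polygon: Polygon, *, return_flag: bool = False
) -> float | tuple[float, bool]:
    """Major-axis (max Feret diameter) orientation of a polygon.

    The angle of the longest chord of the convex hull, from the +x axis,
    reduced mod 180 into ``[0, 180)``. With ``return_flag=True`` also returns
    whether the orientation is unreliable: either the shape is near-round
    (caliper aspect ratio below :data:`LOW_ANISOTROPY_RATIO`) or the longest
    chord is a fully symmetric tie with no preferred direction (a square).
    Flagged cells are still scored; the flag supports sensitivity analyses.
    """
    polygon = repair_polygon(polygon)
    dmax, angle, symmetric_tie = _max_feret_info(polygon)
    if return_flag:
        wmin = min_feret(polygon)
        low = symmetric_tie or wmin <= 0 or (dmax / wmin) < LOW_ANISOTROPY_RATIO
        return angle, low
    return angle


def orientation_from_moments(polygon: Polygon) -> float:
    """Ellipse-moment (second central moment) orientation, for cross-checks.

    Alternative to the Feret-chord definition; agrees closely for elongated
    convex shapes.
    """
    polygon = repair_polygon(polygon)
    pts = np.asarray(polygon.exterior.coords)[:-1]
    # area-weighted second moments via the shoelace decomposition
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    x, xn = x - cx, xn - cx
    y, yn = y - cy, yn - cy
    cross = x * yn - xn * y
    ixx = (cross * (y * y + y * yn + yn * yn)).sum() / 12.0
    iyy = (cross * (x * x + x * xn + xn * xn)).sum() / 12.0
    ixy = (cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)).sum() / 24.0
    if abs(a) < 1e-12:
        raise DegenerateGeometryError("zero-area polygon")
    ixx, iyy, ixy = ixx / a, iyy / a, ixy / a
    return math.degrees(0.5 * math.atan2(2 * ixy, iyy - ixx)) % 180.0
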