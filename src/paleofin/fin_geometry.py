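"""Caudal-fin outline geometry and shape metrics.

A caudal fin is represented as a closed simple polygon digitized from a
lateral-view image (anterior to the left, dorsal up, y-axis pointing up),
with the dorsal and ventral fin-base points marked.  Five dimensionless
shape descriptors are computed from the polygon:

* ``he_wi`` — height-to-width ratio (dorsoventral extent / anteroposterior
  extent of the bounding box);
* ``circ`` — circularity, ``4*pi*area / perimeter**2`` (1 for a circle);
* ``round`` — roundness, ``4*area / (pi*major_axis**2)`` where
  ``major_axis`` is the major-axis length of the ellipse with the same
  second central moments as the filled polygon;
* ``sol`` — solidity, ``area / convex-hull area`` (1 for convex shapes);
* ``ar`` — aspect ratio, ``height**2 / area``.

All five are invariant under similarity transforms of the outline, which is
what makes them usable across specimens digitized at different scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import ConversionError, GeometryError, MaskError

__all__ = [
    "FinOutline",
    "FinMetrics",
    "LengthConversion",
    "outline_from_mask",
    "compute_metrics",
    "to_total_length",
    "read_outline_csv",
    "write_outline_csv",
]

METRIC_NAMES = ("he_wi", "circ", "round", "sol", "ar")

#: column names used in record tables for the five metrics
METRIC_COLUMNS = {
    "HeWiCF": "he_wi",
    "CircCF": "circ",
    "RoundCF": "round",
    "SolCF": "sol",
    "AR": "ar",
}


@dataclass
class FinOutline:
    """Closed polygonal caudal-fin outline in lateral view.

    ``points`` are ordered vertices (the closing edge from the last back to
    the first vertex is implicit).  ``dorsal_base`` and ``ventral_base``
    index the two anatomical (type I) fin-base landmarks; they may be left
    as ``None`` by mask extraction and set afterwards.
    """

    points: np.ndarray
    dorsal_base: int | None = None
    ventral_base: int | None = None
    source_id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise GeometryError("outline points must be an (n, 2) array")
        if len(self.points) < 3:
            raise GeometryError("outline needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise GeometryError("outline contains non-finite coordinates")
        if self.dorsal_base is not None and self.dorsal_base == self.ventral_base:
            raise GeometryError("dorsal and ventral base indices coincide")

    # -- basic quantities -------------------------------------------------
    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def set_fin_base(self, dorsal: int, ventral: int) -> "FinOutline":
        if dorsal == ventral:
            raise GeometryError("dorsal and ventral base indices coincide")
        return replace(self, dorsal_base=int(dorsal), ventral_base=int(ventral))

    def transformed(self, scale=1.0, angle=0.0, shift=(0.0, 0.0)) -> "FinOutline":
        """Apply a similarity transform (used mainly in tests)."""
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        pts = scale * self.points @ rot.T + np.asarray(shift, dtype=float)
        return replace(self, points=pts)


@dataclass(frozen=True)
class FinMetrics:
    """The five dimensionless caudal-fin shape descriptors."""

    he_wi: float
    circ: float
    round: float
    sol: float
    ar: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass(frozen=True)
class LengthConversion:
    """Species-specific linear conversion of standard/fork to total length.

    ``total_cm = slope * measured_cm + intercept``.
    """

    species: str
    kind: str  # "standard->total" or "fork->total"
    slope: float
    intercept: float

    def __post_init__(self):
        if self.slope <= 0:
            raise ConversionError(f"conversion slope must be > 0, got {self.slope}")
        if self.kind not in ("standard->total", "fork->total"):
            raise ConversionError(f"unknown conversion kind {self.kind!r}")


# ---------------------------------------------------------------------------
# mask -> outline


def outline_from_mask(mask: np.ndarray, min_component_px: int = 1) -> FinOutline:
    """Trace the boundary polygon of the single foreground blob of ``mask``.

    The polygon runs through pixel *corners* (crack following), so a filled
    ``k x k`` square yields area exactly ``k**2``.  Coordinates are returned
    with the y-axis pointing up (image row 0 maps to the top).  Exactly one
    connected component of at least ``min_component_px`` pixels must be
    present, and it may not touch all four image borders.
    """
    from skimage import measure as _skmeasure

    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise MaskError("mask must be a 2-D array")
    labels, n = _skmeasure.label(mask, connectivity=1, return_num=True)
    sizes = np.bincount(labels.ravel())[1:]
    keep = [i + 1 for i, s in enumerate(sizes) if s >= min_component_px]
    if len(keep) == 0:
        raise MaskError("mask contains no foreground component of sufficient size")
    if len(keep) > 1:
        raise MaskError(f"mask contains {len(keep)} foreground components, expected 1")
    comp = labels == keep[0]
    rows, cols = np.nonzero(comp)
    h, w = mask.shape
    if rows.min() == 0 and rows.max() == h - 1 and cols.min() == 0 and cols.max() == w - 1:
        raise MaskError("foreground component touches all four image borders")

    poly = _pixel_boundary_polygon(comp)
    # flip to y-up: y = n_rows - row_coordinate
    pts = np.column_stack([poly[:, 1], h - poly[:, 0]])
    # ensure counter-clockwise in the y-up frame
    out = FinOutline(pts)
    if out.signed_area < 0:
        out = replace(out, points=pts[::-1].copy())
    return out


def _pixel_boundary_polygon(comp: np.ndarray) -> np.ndarray:
    """Exterior boundary of a pixel set as a polygon through pixel corners.

    Returns vertices in (row, col) corner coordinates.  Implemented by
    dissolving the unit squares of the component with shapely; exact for
    axis-aligned pixel geometry.
    """
    import shapely

    rows, cols = np.nonzero(comp)
    boxes = shapely.box(cols, rows, cols + 1, rows + 1)
    merged = shapely.unary_union(boxes)
    if merged.geom_type == "MultiPolygon":  # pragma: no cover - guarded by caller
        raise MaskError("component dissolved into multiple polygons")
    xy = np.asarray(merged.exterior.coords)[:-1]  # drop repeated closing vertex
    return np.column_stack([xy[:, 1], xy[:, 0]])


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(outline: FinOutline) -> FinMetrics:
    """Compute the five shape descriptors of a fin outline.

    Area uses the shoelace formula, the perimeter is the polyline length,
    the convex area comes from the hull of the vertices, and the major axis
    is that of the second-moment equivalent ellipse of the filled polygon.
    Height is the bounding extent along y (dorsoventral), width along x.
    """
    pts = outline.points
    area = abs(outline.signed_area)
    if area <= 0 or not np.isfinite(area):
        raise GeometryError("degenerate (zero-area) polygon")
    perim = outline.perimeter
    width = float(pts[:, 0].max() - pts[:, 0].min())
    height = float(pts[:, 1].max() - pts[:, 1].min())
    if width <= 0 or height <= 0:
        raise GeometryError("outline has zero extent along an axis")
    hull_area = float(ConvexHull(pts).volume)
    major = _major_axis_length(pts)

    return FinMetrics(
        he_wi=height / width,
        circ=4.0 * math.pi * area / perim**2,
        round=4.0 * area / (math.pi * major**2),
        sol=area / hull_area,
        ar=height**2 / area,
    )


def _polygon_moments(pts: np.ndarray):
    """Area, centroid and second central moments of a simple polygon.

    Standard Green's-theorem formulas for a polygon treated as a uniform
    lamina; works for either vertex orientation.
    """
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    # second moments about the origin
    ixx = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    iyy = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    # central moments, normalized by area (variance-like)
    mxx = iyy / a - cx * cx
    myy = ixx / a - cy * cy
    mxy = ixy / a - cx * cy
    return abs(a), (cx, cy), (mxx, myy, mxy)


def _major_axis_length(pts: np.ndarray) -> float:
    """Major-axis length of the second-moment equivalent ellipse."""
    _, _, (mxx, myy, mxy) = _polygon_moments(pts)
    common = math.sqrt(max((mxx - myy) ** 2 + 4 * mxy**2, 0.0))
    lam = 0.5 * (mxx + myy + common)  # larger eigenvalue of the covariance
    if lam <= 0:
        raise GeometryError("degenerate second-moment ellipse")
    # for an ellipse with semi-axes (p, q): variance along major axis = p^2/4
    return 4.0 * math.sqrt(lam)


def is_simple(outline: FinOutline) -> bool:
    """True if the closed polygon does not self-intersect."""
    return bool(_ShapelyPolygon(outline.points).is_simple)


# ---------------------------------------------------------------------------
# length conversion


def to_total_length(value: float, conv: LengthConversion) -> float:
    """Convert a standard/fork length measurement (cm) to total length (cm)."""
    if value <= 0:
        raise ConversionError(f"measured length must be > 0, got {value}")
    total = conv.slope * value + conv.intercept
    if total <= 0:
        raise ConversionError(
            f"conversion for {conv.species!r} yields non-positive total length {total:.3g}"
        )
    return total


def read_length_conversions(path) -> dict[str, LengthConversion]:
    """Read a CSV ``species,kind,slope,intercept`` table."""
    import pandas as pd

    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        out[row.species] = LengthConversion(
            species=row.species, kind=row.kind, slope=float(row.slope), intercept=float(row.intercept)
        )
    return out


# ---------------------------------------------------------------------------
# outline I/O (polygon CSV)


def write_outline_csv(outline: FinOutline, path) -> None:
    """Write an outline as an ``x,y`` CSV; base indices go into a header comment."""
    path = Path(path)
    lines = ["x,y"]
    if outline.dorsal_base is not None:
        lines[0] = f"# dorsal_base={outline.dorsal_base} ventral_base={outline.ventral_base}\nx,y"
    for x, y in outline.points:
        lines.append(f"{float(x)!r},{float(y)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_outline_csv(path) -> FinOutline:
    path = Path(path)
    dorsal = ventral = None
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = dict(p.split("=") for p in line[1:].split())
            dorsal = int(parts.get("dorsal_base", -1))
            ventral = int(parts.get("ventral_base", -1))
            continue
        if line.lower().startswith("x,"):
            continue
        x, y = line.split(",")
        rows.append((float(x), float(y)))
    return FinOutline(np.array(rows), dorsal_base=dorsal, ventral_base=ventral, source_id=path.stem)
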