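"""Regions of interest on planar MIBG images.

Four ROI geometries are used in planar MIBG quantification:

* a manually drawn **polygon** over the myocardium including the left
  ventricular cavity (the conventional cardiac ROI),
* a 13 x 20 pixel **rectangle** on the upper mediastinum, placed from
  anatomical landmarks (lung apexes, upper cardiac border, medial lung
  contours),
* a fixed-size **oval** of 60 x 70 pixels with its long axis along the heart
  axis (alternative cardiac ROI),
* a fixed-size **circle** of radius 21 pixels at the cardiac apex
  (alternative cardiac ROI).

Coordinate convention
---------------------
0-based ``(row, col)`` coordinates with pixel centers at integer positions;
geometry may be real-valued.  A pixel belongs to an ROI iff its *center* lies
inside the region, with boundary-inclusive comparisons (``<=`` against
circle/oval/rectangle boundaries; points on a polygon edge count as inside,
interior membership otherwise by the even-odd rule).  There is no
partial-pixel weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np

from .image import PlanarImage

__all__ = [
    "PolygonROI",
    "RectangleROI",
    "OvalROI",
    "CircleROI",
    "ROI",
    "ROIStats",
    "LandmarkSquare",
    "ROISet",
    "RasterizationError",
    "rasterize",
    "roi_stats",
    "translate",
    "place_mediastinal_roi",
    "place_oval_cardiac_roi",
    "place_circular_cardiac_roi",
    "roi_to_dict",
    "roi_from_dict",
    "save_roi_set",
    "load_roi_set",
]

#: tolerance for "pixel center exactly on the boundary" decisions
_EDGE_EPS = 1e-9

#: protocol constants: mediastinal rectangle 13 columns x 20 rows,
#: oval semi-axes (35, 30) px (60 x 70 px bounding box), circle radius 21 px
MEDIASTINAL_WIDTH_PX = 13
MEDIASTINAL_HEIGHT_PX = 20
OVAL_SEMI_AXES_PX = (35.0, 30.0)
CIRCLE_RADIUS_PX = 21.0


class RasterizationError(ValueError):
    """Raised when an ROI cannot be resolved to a non-empty pixel mask."""


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper or improper intersection test for segments p1p2 and p3p4."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(v) < 1e-12:
            return 0
        return 1 if v > 0 else -1

    def on_seg(a, b, c):
        return (
            min(a[0], b[0]) - 1e-12 <= c[0] <= max(a[0], b[0]) + 1e-12
            and min(a[1], b[1]) - 1e-12 <= c[1] <= max(a[1], b[1]) + 1e-12
        )

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    if o1 != o2 and o3 != o4:
        return True
    if o1 == 0 and on_seg(p1, p2, p3):
        return True
    if o2 == 0 and on_seg(p1, p2, p4):
        return True
    if o3 == 0 and on_seg(p3, p4, p1):
        return True
    if o4 == 0 and on_seg(p3, p4, p2):
        return True
    return False


@dataclass(frozen=True)
class PolygonROI:
    """Manually drawn cardiac ROI: a simple polygon given by ordered vertices.

    ``vertices`` is a sequence of real-valued ``(row, col)`` pairs, at least
    three, describing a non-self-intersecting closed contour.
    """

    vertices: tuple[tuple[float, float], ...]
    kind: str = "polygon"

    def __post_init__(self) -> None:
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        m = len(verts)
        edges = [(verts[i], verts[(i + 1) % m]) for i in range(m)]
        for i in range(m):
            for j in range(i + 1, m):
                if j == i + 1 or (i == 0 and j == m - 1):
                    continue  # adjacent edges share a vertex by construction
                if _segments_intersect(*edges[i], *edges[j]):
                    raise ValueError("polygon is self-intersecting")


@dataclass(frozen=True)
class RectangleROI:
    """Axis-aligned rectangle; ``top_left`` addresses its first pixel center.

    The mask covers pixel centers ``(r, c)`` with
    ``top_left[0] <= r <= top_left[0] + height - 1`` and analogously for
    columns, so an integer-placed 13 x 20 rectangle contains exactly 260
    pixels.
    """

    top_left: tuple[float, float]
    width: float  # columns
    height: float  # rows
    kind: str = "rectangle"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("rectangle dimensions must be positive")
        object.__setattr__(self, "top_left", (float(self.top_left[0]), float(self.top_left[1])))


@dataclass(frozen=True)
class OvalROI:
    """Fixed-size oval cardiac ROI.

    ``semi_axes = (along, across)``: the first semi-axis lies along the axis
    direction obtained by rotating the image-vertical (row) direction by
    ``angle_deg`` toward increasing columns; the second is perpendicular.
    For the cardiac oval the long axis (35 px) is aligned with the heart axis.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float] = OVAL_SEMI_AXES_PX
    angle_deg: float = 0.0
    kind: str = "oval"

    def __post_init__(self) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError("oval semi-axes must be positive")
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))
        object.__setattr__(self, "semi_axes", (float(self.semi_axes[0]), float(self.semi_axes[1])))


@dataclass(frozen=True)
class CircleROI:
    """Fixed-size circular cardiac ROI placed at the apex."""

    center: tuple[float, float]
    radius: float = CIRCLE_RADIUS_PX
    kind: str = "circle"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("circle radius must be positive")
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))


ROI = Union[PolygonROI, RectangleROI, OvalROI, CircleROI]


@dataclass(frozen=True)
class ROIStats:
    """Count statistics over an ROI mask.

    ``mean_counts`` is the quantity the H/M and washout formulas call *H*
    (cardiac ROI) or *M* (mediastinal ROI): average counts per pixel inside
    the mask.  No background correction is applied.
    """

    mean_counts: float
    pixel_count: int
    total_counts: float


@dataclass(frozen=True)
class LandmarkSquare:
    """Anatomical landmark square for mediastinal ROI placement.

    Bounded above by the lung apexes, below by the upper cardiac border and
    laterally by the medial contours of the lungs (all in pixel coordinates,
    rows increasing downward).
    """

    apex_row: float
    cardiac_border_row: float
    left_col: float
    right_col: float

    def __post_init__(self) -> None:
        if not self.apex_row < self.cardiac_border_row:
            raise ValueError("apex_row must be above cardiac_border_row")
        if not self.left_col < self.right_col:
            raise ValueError("left_col must be left of right_col")


@dataclass
class ROISet:
    """The full set of ROIs for one study, as drawn by one observer.

    Carries the polygon and the landmark-derived mediastinal rectangle plus
    the two fixed-size cardiac ROI placements, with the geometric quantities
    (heart-axis angle, apex location, landmarks) they were derived from.
    """

    cardiac_polygon: PolygonROI
    mediastinal_rect: RectangleROI
    cardiac_oval: OvalROI
    cardiac_circle: CircleROI
    landmarks: LandmarkSquare
    heart_axis_angle_deg: float
    apex: tuple[float, float]

    def cardiac(self, mode: str) -> ROI:
        """Return the cardiac ROI for ``mode`` in {'polygon','oval','circle'}."""
        try:
            return {
                "polygon": self.cardiac_polygon,
                "oval": self.cardiac_oval,
                "circle": self.cardiac_circle,
            }[mode]
        except KeyError:
            raise ValueError(f"unknown cardiac ROI mode {mode!r}") from None


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _bbox_indices(rmin, rmax, cmin, cmax, shape):
    r0 = max(0, int(np.ceil(rmin - _EDGE_EPS)))
    r1 = min(shape[0] - 1, int(np.floor(rmax + _EDGE_EPS)))
    c0 = max(0, int(np.ceil(cmin - _EDGE_EPS)))
    c1 = min(shape[1] - 1, int(np.floor(cmax + _EDGE_EPS)))
    return r0, r1, c0, c1


def _polygon_mask(roi: PolygonROI, shape) -> np.ndarray:
    verts = np.asarray(roi.vertices, dtype=float)
    r0, r1, c0, c1 = _bbox_indices(
        verts[:, 0].min(), verts[:, 0].max(), verts[:, 1].min(), verts[:, 1].max(), shape
    )
    mask = np.zeros(shape, dtype=bool)
    if r1 < r0 or c1 < c0:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    py = rr.astype(float)
    px = cc.astype(float)
    inside = np.zeros(py.shape, dtype=bool)
    on_edge = np.zeros(py.shape, dtype=bool)
    m = len(verts)
    for i in range(m):
        y1, x1 = verts[i]
        y2, x2 = verts[(i + 1) % m]
        # even-odd crossing count against a ray toward +col
        cond = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (px < xint)
        # boundary inclusion: distance from pixel center to the segment
        ey, ex = y2 - y1, x2 - x1
        L2 = ey * ey + ex * ex
        if L2 == 0:
            d2 = (py - y1) ** 2 + (px - x1) ** 2
        else:
            t = np.clip(((py - y1) * ey + (px - x1) * ex) / L2, 0.0, 1.0)
            d2 = (py - (y1 + t * ey)) ** 2 + (px - (x1 + t * ex)) ** 2
        on_edge |= d2 <= _EDGE_EPS**2
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside | on_edge
    return mask


def _rectangle_mask(roi: RectangleROI, shape) -> np.ndarray:
    rt, ct = roi.top_left
    r0, r1, c0, c1 = _bbox_indices(rt, rt + roi.height - 1, ct, ct + roi.width - 1, shape)
    mask = np.zeros(shape, dtype=bool)
    if r1 >= r0 and c1 >= c0:
        mask[r0 : r1 + 1, c0 : c1 + 1] = True
    return mask


def _oval_mask(roi: OvalROI, shape) -> np.ndarray:
    a, b = roi.semi_axes
    rc, cc_ = roi.center
    ext = max(a, b)
    r0, r1, c0, c1 = _bbox_indices(rc - ext, rc + ext, cc_ - ext, cc_ + ext, shape)
    mask = np.zeros(shape, dtype=bool)
    if r1 < r0 or c1 < c0:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    th = np.deg2rad(roi.angle_deg)
    dr = rr - rc
    dc = cc - cc_
    u = dr * np.cos(th) + dc * np.sin(th)  # along-axis coordinate
    v = -dr * np.sin(th) + dc * np.cos(th)
    mask[r0 : r1 + 1, c0 : c1 + 1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0 + _EDGE_EPS
    return mask


def _circle_mask(roi: CircleROI, shape) -> np.ndarray:
    rc, cc_ = roi.center
    r = roi.radius
    r0, r1, c0, c1 = _bbox_indices(rc - r, rc + r, cc_ - r, cc_ + r, shape)
    mask = np.zeros(shape, dtype=bool)
    if r1 < r0 or c1 < c0:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    mask[r0 : r1 + 1, c0 : c1 + 1] = (rr - rc) ** 2 + (cc - cc_) ** 2 <= r * r + _EDGE_EPS
    return mask


def rasterize(roi: ROI, image_shape: tuple[int, int]) -> np.ndarray:
    """Resolve an ROI to a boolean pixel mask on an image of ``image_shape``.

    A pixel is in the mask iff its center lies inside the region
    (boundary-inclusive).  Deterministic; raises :class:`RasterizationError`
    if no pixel center falls inside the region.
    """
    if isinstance(roi, PolygonROI):
        mask = _polygon_mask(roi, image_shape)
    elif isinstance(roi, RectangleROI):
        mask = _rectangle_mask(roi, image_shape)
    elif isinstance(roi, OvalROI):
        mask = _oval_mask(roi, image_shape)
    elif isinstance(roi, CircleROI):
        mask = _circle_mask(roi, image_shape)
    else:  # pragma: no cover - defensive
        raise TypeError(f"unknown ROI type {type(roi)!r}")
    if not mask.any():
        raise RasterizationError("ROI covers no pixels")
    return mask


def translate(roi: ROI, d_row: float, d_col: float) -> ROI:
    """Return a copy of ``roi`` translated by ``(d_row, d_col)``."""
    if isinstance(roi, PolygonROI):
        return replace(roi, vertices=tuple((r + d_row, c + d_col) for r, c in roi.vertices))
    if isinstance(roi, RectangleROI):
        return replace(roi, top_left=(roi.top_left[0] + d_row, roi.top_left[1] + d_col))
    if isinstance(roi, (OvalROI, CircleROI)):
        return replace(roi, center=(roi.center[0] + d_row, roi.center[1] + d_col))
    raise TypeError(f"unknown ROI type {type(roi)!r}")


def roi_extent(roi: ROI) -> tuple[float, float, float, float]:
    """(row_min, row_max, col_min, col_max) bounding extent of the geometry."""
    if isinstance(roi, PolygonROI):
        v = np.asarray(roi.vertices)
        return v[:, 0].min(), v[:, 0].max(), v[:, 1].min(), v[:, 1].max()
    if isinstance(roi, RectangleROI):
        rt, ct = roi.top_left
        return rt, rt + roi.height - 1, ct, ct + roi.width - 1
    if isinstance(roi, OvalROI):
        a, b = roi.semi_axes
        th = np.deg2rad(roi.angle_deg)
        # exact extents of a rotated ellipse
        dr = np.hypot(a * np.cos(th), b * np.sin(th))
        dc = np.hypot(a * np.sin(th), b * np.cos(th))
        return roi.center[0] - dr, roi.center[0] + dr, roi.center[1] - dc, roi.center[1] + dc
    if isinstance(roi, CircleROI):
        r = roi.radius
        return roi.center[0] - r, roi.center[0] + r, roi.center[1] - r, roi.center[1] + r
    raise TypeError(f"unknown ROI type {type(roi)!r}")


def fits_in_frame(roi: ROI, image_shape: tuple[int, int]) -> bool:
    """True if the ROI geometry lies fully inside the pixel-center frame."""
    rmin, rmax, cmin, cmax = roi_extent(roi)
    return rmin >= 0 and cmin >= 0 and rmax <= image_shape[0] - 1 and cmax <= image_shape[1] - 1


# ---------------------------------------------------------------------------
# placement rules
# ---------------------------------------------------------------------------

def place_mediastinal_roi(
    landmarks: LandmarkSquare,
    width: int = MEDIASTINAL_WIDTH_PX,
    height: int = MEDIASTINAL_HEIGHT_PX,
    row_offset: float = 0.0,
) -> RectangleROI:
    """Place the 13 x 20 px mediastinal rectangle from anatomical landmarks.

    The rectangle is horizontally centered between the medial lung contours
    and anchored with its top edge at the lung-apex row (the upper half of the
    landmark square), optionally shifted down by ``row_offset``.  When exact
    centering is impossible (odd column slack) the tie is broken toward the
    smaller column.
    """
    span_cols = landmarks.right_col - landmarks.left_col + 1
    span_rows = landmarks.cardiac_border_row - landmarks.apex_row + 1
    if span_cols < width:
        raise ValueError(
            f"landmark square is {span_cols:g} px wide; need at least {width} for the mediastinal ROI"
        )
    if span_rows < height:
        raise ValueError(
            f"landmark square is {span_rows:g} px tall; need at least {height} for the mediastinal ROI"
        )
    c0 = landmarks.left_col + np.floor((span_cols - width) / 2.0)
    r0 = landmarks.apex_row + row_offset
    return RectangleROI(top_left=(r0, c0), width=width, height=height)


def place_oval_cardiac_roi(
    center: tuple[float, float],
    heart_axis_angle_deg: float,
    image_shape: tuple[int, int],
    semi_axes: tuple[float, float] = OVAL_SEMI_AXES_PX,
) -> OvalROI:
    """Place the fixed-size oval cardiac ROI with its long axis on the heart axis."""
    roi = OvalROI(center=center, semi_axes=semi_axes, angle_deg=heart_axis_angle_deg)
    if not fits_in_frame(roi, image_shape):
        raise ValueError("oval cardiac ROI extends outside the image frame")
    return roi


def place_circular_cardiac_roi(
    apex_center: tuple[float, float],
    image_shape: tuple[int, int],
    radius: float = CIRCLE_RADIUS_PX,
) -> CircleROI:
    """Place the fixed-size circular cardiac ROI at the cardiac apex."""
    roi = CircleROI(center=apex_center, radius=radius)
    if not fits_in_frame(roi, image_shape):
        raise ValueError("circular cardiac ROI extends outside the image frame")
    return roi


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def roi_stats(image: PlanarImage, roi: ROI) -> ROIStats:
    """Mean / total counts and pixel count of ``roi`` on ``image``.

    No background correction is applied: the mean is the plain average of the
    raw counts over the mask.
    """
    mask = rasterize(roi, image.shape)
    vals = image.counts[mask]
    total = float(vals.sum())
    n = int(mask.sum())
    return ROIStats(mean_counts=total / n, pixel_count=n, total_counts=total)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def roi_to_dict(roi: ROI) -> dict:
    if isinstance(roi, PolygonROI):
        return {"kind": "polygon", "vertices": [list(v) for v in roi.vertices]}
    if isinstance(roi, RectangleROI):
        return {
            "kind": "rectangle",
            "top_left": list(roi.top_left),
            "width": roi.width,
            "height": roi.height,
        }
    if isinstance(roi, OvalROI):
        return {
            "kind": "oval",
            "center": list(roi.center),
            "semi_axes": list(roi.semi_axes),
            "angle_deg": roi.angle_deg,
        }
    if isinstance(roi, CircleROI):
        return {"kind": "circle", "center": list(roi.center), "radius": roi.radius}
    raise TypeError(f"unknown ROI type {type(roi)!r}")


def roi_from_dict(d: dict) -> ROI:
    kind = d.get("kind")
    if kind == "polygon":
        return PolygonROI(vertices=tuple(tuple(v) for v in d["vertices"]))
    if kind == "rectangle":
        return RectangleROI(top_left=tuple(d["top_left"]), width=d["width"], height=d["height"])
    if kind == "oval":
        return OvalROI(
            center=tuple(d["center"]),
            semi_axes=tuple(d["semi_axes"]),
            angle_deg=d.get("angle_deg", 0.0),
        )
    if kind == "circle":
        return CircleROI(center=tuple(d["center"]), radius=d["radius"])
    raise ValueError(f"unknown ROI kind {kind!r}")


def roi_set_to_dict(rois: ROISet) -> dict:
    return {
        "cardiac_polygon": roi_to_dict(rois.cardiac_polygon),
        "mediastinal_rect": roi_to_dict(rois.mediastinal_rect),
        "cardiac_oval": roi_to_dict(rois.cardiac_oval),
        "cardiac_circle": roi_to_dict(rois.cardiac_circle),
        "landmarks": {
            "apex_row": rois.landmarks.apex_row,
            "cardiac_border_row": rois.landmarks.cardiac_border_row,
            "left_col": rois.landmarks.left_col,
            "right_col": rois.landmarks.right_col,
        },
        "heart_axis_angle_deg": rois.heart_axis_angle_deg,
        "apex": list(rois.apex),
    }


def roi_set_from_dict(d: dict) -> ROISet:
    return ROISet(
        cardiac_polygon=roi_from_dict(d["cardiac_polygon"]),
        mediastinal_rect=roi_from_dict(d["mediastinal_rect"]),
        cardiac_oval=roi_from_dict(d["cardiac_oval"]),
        cardiac_circle=roi_from_dict(d["cardiac_circle"]),
        landmarks=LandmarkSquare(**d["landmarks"]),
        heart_axis_angle_deg=d["heart_axis_angle_deg"],
        apex=tuple(d["apex"]),
    )


def save_roi_set(path: str | Path, rois: ROISet) -> None:
    Path(path).write_text(json.dumps(roi_set_to_dict(rois), indent=1))


def load_roi_set(path: str | Path) -> ROISet:
    return roi_set_from_dict(json.loads(Path(path).read_text()))
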