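"""Per-instance geometry of binary tumour masks.

A segmenter (any external one; this package does not segment) produces a
binary mask of lesion pixels.  This module turns such a mask into
per-instance measurements: 8-connected instance labelling, clockwise Moore
boundary tracing, a monotone-chain convex hull, the maximum Euclidean
distance between pixel centres (max Feret diameter, found on hull vertices
by rotating calipers), and optional conversion to physical units through a
linear calibration.

Conventions
-----------
* Coordinates are 0-based ``(row, col)`` integers; distances are Euclidean
  between pixel centres, in pixel units.
* Foreground is 8-connected; the background complement is 4-connected.
* A boundary pixel is a foreground pixel with at least one 4-neighbour that
  is background or that lies outside the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .calibration import CalibrationModel

__all__ = [
    "TumourInstance",
    "MorphometryRecord",
    "label_instances",
    "extract_boundary",
    "convex_hull",
    "max_pixel_distance",
    "measure_mask",
    "validate_mask",
]

#: Pixels below this area are treated as segmentation speckle by default.
DEFAULT_MIN_AREA_PX = 5

_N8 = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element

# Moore neighbourhood in clockwise screen order (row grows downwards),
# starting at the western neighbour.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Coerce *mask* to a 2-D boolean array, rejecting invalid shapes."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("mask must be a 2-D array with positive dimensions")
    return arr.astype(bool)


@dataclass
class TumourInstance:
    """One 8-connected foreground component of a mask."""

    id: int
    pixels: np.ndarray          # (N, 2) int array of (row, col)
    boundary: list = field(default_factory=list)  # ordered [(row, col), ...]

    @property
    def area_px(self) -> int:
        return int(len(self.pixels))


@dataclass
class MorphometryRecord:
    """Geometric measurements of a single instance.

    Physical fields are populated only when a calibration model was supplied;
    ``est_volume_phys`` assumes a sphere of the calibrated max diameter and is
    flagged as such in serialized output.
    """

    instance_id: int
    area_px: int
    max_diameter_px: float
    endpoints: tuple            # ((row, col), (row, col)) attaining the diameter
    max_diameter_phys: Optional[float] = None
    area_phys: Optional[float] = None
    est_volume_phys: Optional[float] = None
    volume_model: str = "sphere (pi/6 * d^3), estimated"

    def to_dict(self) -> dict:
        (r1, c1), (r2, c2) = self.endpoints
        return {
            "instance_id": self.instance_id,
            "area_px": self.area_px,
            "max_diameter_px": self.max_diameter_px,
            "endpoint1_row": int(r1),
            "endpoint1_col": int(c1),
            "endpoint2_row": int(r2),
            "endpoint2_col": int(c2),
            "max_diameter_phys": self.max_diameter_phys,
            "area_phys": self.area_phys,
            "est_volume_phys": self.est_volume_phys,
            "volume_model": self.volume_model,
        }


def label_instances(mask: np.ndarray, min_area_px: int = DEFAULT_MIN_AREA_PX
                    ) -> list[TumourInstance]:
    """Split *mask* into 8-connected instances of area >= *min_area_px*.

    Instances are labelled 1..k in raster-scan order of their first pixel.
    An all-background mask yields an empty list.
    """
    mask = validate_mask(mask)
    if min_area_px < 0:
        raise ValueError("min_area_px must be non-negative")
    labelled, n = ndimage.label(mask, structure=_N8)
    if n == 0:
        return []
    # Re-label by scan order of each component's first pixel so ids are
    # deterministic regardless of the labelling library's internal order.
    flat = labelled.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    # reversed so the smallest index wins
    first[flat[idx[::-1]]] = idx[::-1]
    order = np.argsort(first[1:], kind="stable")
    instances: list[TumourInstance] = []
    next_id = 1
    for old_label in order + 1:
        rows, cols = np.nonzero(labelled == old_label)
        if rows.size < min_area_px:
            continue
        pixels = np.column_stack([rows, cols]).astype(np.int64)
        inst = TumourInstance(id=next_id, pixels=pixels)
        inst.boundary = extract_boundary(inst, mask)
        instances.append(inst)
        next_id += 1
    return instances


def _boundary_set(sub: np.ndarray) -> set:
    """4-neighbour/edge boundary pixels of a padded instance mask."""
    interior = ndimage.binary_erosion(
        sub, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
        border_value=0)
    rows, cols = np.nonzero(sub & ~interior)
    return set(zip(rows.tolist(), cols.tolist()))


def _moore_trace(sub: np.ndarray, start: tuple, back: tuple) -> list:
    """Clockwise Moore-neighbourhood contour trace on a padded mask.

    *back* is a background 4-neighbour of *start* that fixes which contour
    (outer or a hole) is followed.  Terminates when the (pixel, backtrack)
    state recurs, which also handles single-pixel and one-pixel-wide shapes.
    """
    h, w = sub.shape

    def neighbours_from(p, b):
        dr, dc = b[0] - p[0], b[1] - p[1]
        k = _MOORE.index((dr, dc))
        for step in range(1, 9):
            dr, dc = _MOORE[(k + step) % 8]
            yield (p[0] + dr, p[1] + dc)

    trace: list = []
    p, b = start, back
    init = (start, back)
    cap = 8 * int(sub.sum()) + 8
    while True:
        prev = b
        nxt = None
        for q in neighbours_from(p, b):
            if 0 <= q[0] < h and 0 <= q[1] < w and sub[q]:
                nxt = q
                break
            prev = q
        if nxt is None:                       # isolated pixel
            return [start]
        trace.append(p)
        p, b = nxt, prev
        if (p, b) == init or len(trace) > cap:
            return trace


def extract_boundary(instance: TumourInstance, mask: np.ndarray) -> list:
    """Ordered clockwise boundary trace of *instance*.

    The returned pixel set equals exactly the set of instance pixels having a
    background 4-neighbour or touching the image edge.  The outer contour is
    traced first (Moore neighbourhood, clockwise in screen convention,
    starting from the raster-first boundary pixel); contours of interior
    holes, if any, follow in scan order of their first pixel.
    """
    mask = validate_mask(mask)
    pixels = np.asarray(instance.pixels)
    r0, c0 = pixels.min(axis=0)
    r1, c1 = pixels.max(axis=0)
    sub = np.zeros((r1 - r0 + 3, c1 - c0 + 3), dtype=bool)  # 1-px pad
    sub[pixels[:, 0] - r0 + 1, pixels[:, 1] - c0 + 1] = True

    wanted = _boundary_set(sub)
    if not wanted:
        return []
    ordered: list = []
    emitted: set = set()
    remaining = set(wanted)
    while remaining:
        start = min(remaining)
        # pick a background 4-neighbour as the backtrack pixel
        back = None
        for dr, dc in ((0, -1), (-1, 0), (0, 1), (1, 0)):
            q = (start[0] + dr, start[1] + dc)
            if not sub[q]:
                back = q
                break
        if back is None:
            # only diagonal background contact: not part of the 4-boundary
            remaining.discard(start)
            continue
        for p in _moore_trace(sub, start, back):
            if p in wanted and p not in emitted:
                emitted.add(p)
                ordered.append(p)
        remaining -= emitted
        remaining.discard(start)
    return [(int(r + r0 - 1), int(c + c0 - 1)) for r, c in ordered]


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points: Sequence) -> list:
    """Convex hull of (row, col) points by the monotone-chain method.

    Returns the extreme points in counter-clockwise order (treating row as x
    and col as y).  Duplicates are removed; collinear non-extreme points are
    excluded so the vertex set is deterministic.  One point yields a
    single-vertex "polygon"; two distinct points yield a segment.
    """
    pts = sorted({(float(p[0]), float(p[1])) for p in points})
    if not pts:
        raise ValueError("no points")
    if len(pts) <= 2:
        return pts

    def half(seq):
        out = []
        for p in seq:
            while len(out) >= 2 and _cross(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    lower = half(pts)
    upper = half(reversed(pts))
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:            # all input points collinear
        return [pts[0], pts[-1]]
    return hull


def point_in_hull(point, hull: Sequence, tol: float = 1e-9) -> bool:
    """Inside-or-on test against a CCW convex polygon (or segment/point)."""
    p = (float(point[0]), float(point[1]))
    if len(hull) == 1:
        return abs(p[0] - hull[0][0]) <= tol and abs(p[1] - hull[0][1]) <= tol
    if len(hull) == 2:
        a, b = hull
        if abs(_cross(a, b, p)) > tol * (1 + math.dist(a, b)):
            return False
        lo = min(a, b)
        hi = max(a, b)
        return lo[0] - tol <= p[0] <= hi[0] + tol and \
            min(a[1], b[1]) - tol <= p[1] <= max(a[1], b[1]) + tol
    n = len(hull)
    for i in range(n):
        if _cross(hull[i], hull[(i + 1) % n], p) < -tol:
            return False
    return True


def _sq(a, b) -> float:
    dr = a[0] - b[0]
    dc = a[1] - b[1]
    return dr * dr + dc * dc


def _best_pair(pairs) -> tuple:
    """Max-distance pair with lexicographically smallest sorted endpoints."""
    best_d = -1.0
    best = None
    for a, b in pairs:
        d = _sq(a, b)
        pair = (a, b) if a <= b else (b, a)
        if d > best_d or (d == best_d and pair < best):
            best_d = d
            best = pair
    return best_d, best


def max_pixel_distance(hull: Sequence) -> tuple:
    """Maximum Euclidean distance between hull vertices and its endpoints.

    Rotating calipers over antipodal pairs when the hull is a true polygon,
    brute force for degenerate hulls.  By convexity this equals the maximum
    over all points of the originating region.  Ties are broken by the
    lexicographically smallest endpoint pair; a single vertex gives distance
    0 with identical endpoints.
    """
    verts = [tuple(map(float, v)) for v in hull]
    if not verts:
        raise ValueError("no points")
    if len(verts) == 1:
        return 0.0, (verts[0], verts[0])
    if len(verts) == 2:
        d2, pair = _best_pair([(verts[0], verts[1])])
        return math.sqrt(d2), pair

    n = len(verts)
    candidates = []
    j = 1
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        # advance j while the triangle area keeps growing (antipodal search)
        while True:
            nj = (j + 1) % n
            if abs(_cross(a, b, verts[nj])) > abs(_cross(a, b, verts[j])):
                j = nj
            else:
                break
        candidates.append((a, verts[j]))
        candidates.append((b, verts[j]))
    d2, pair = _best_pair(candidates)
    return math.sqrt(d2), pair


def measure_mask(mask: np.ndarray,
                 min_area_px: int = DEFAULT_MIN_AREA_PX,
                 calibration: Optional[CalibrationModel] = None
                 ) -> list[MorphometryRecord]:
    """Full pipeline: label -> boundary -> hull -> max distance [-> calibrate].

    With a calibration (slope in mm/px), lengths map as
    ``slope * px + intercept``; areas scale by ``slope**2`` (the intercept
    applies to lengths only); the estimated volume is a sphere of the
    calibrated max diameter, (pi/6) d^3.  The tumour count of the image is
    the number of records returned.
    """
    records = []
    for inst in label_instances(mask, min_area_px=min_area_px):
        hull = convex_hull(inst.boundary)
        dist, endpoints = max_pixel_distance(hull)
        rec = MorphometryRecord(
            instance_id=inst.id,
            area_px=inst.area_px,
            max_diameter_px=dist,
            endpoints=endpoints,
        )
        if calibration is not None:
            d_phys = calibration.apply(dist)
            rec.max_diameter_phys = d_phys
            rec.area_phys = calibration.slope ** 2 * inst.area_px
            rec.est_volume_phys = math.pi / 6.0 * d_phys ** 3
        records.append(rec)
    return records
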