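"""Convex hull-scan repair of fragmented vein masks.

Segmentation of a creased leaf frequently breaks the main vein into
fragments separated by occlusion gaps.  The repair strategy is purely
geometric: locate nearby fragment pairs, take the Graham-scan convex hull
of the boundary points around the gap (plus any small noise components in
the same window), rasterize and scanline-fill that polygon, and union the
filled polygon back into the mask.  Computing hulls over local gap windows
rather than the whole mask keeps curved veins from being convexified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .imagecore import as_mask, bitwise_or, boundary_pixels, connected_components

__all__ = [
    "RepairParams",
    "cross_turn",
    "graham_hull",
    "fill_polygon",
    "find_repair_regions",
    "repair_mask",
]


@dataclass(frozen=True)
class RepairParams:
    """Tunables of the gap-detection step.

    max_gap_px
        Largest fragment-to-fragment boundary distance that is bridged.
    min_fragment_px
        Components smaller than this area are treated as noise points /
        small isolated regions and swept into a nearby gap's hull.
    window_margin_px
        Margin added around the two nearest boundary points when
        collecting the local point set of a gap.
    """

    max_gap_px: float = 40.0
    min_fragment_px: int = 25
    window_margin_px: int = 10

    def __post_init__(self) -> None:
        if self.max_gap_px <= 0 or self.min_fragment_px <= 0 or self.window_margin_px <= 0:
            raise ValueError("all repair parameters must be strictly positive")


def cross_turn(a, b, c) -> float:
    """2D cross product (b - a) x (c - a).

    Positive means a counterclockwise turn at *b* (candidate vertex is
    kept), negative a clockwise turn (the stack top is popped), zero
    collinear.  Points are (x, y) pairs.
    """
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def graham_hull(points) -> list[tuple[int, int]]:
    """Graham-scan convex hull of a set of (x, y) points.

    The anchor is the point of minimal x (ties broken by minimal y); the
    remaining points are sorted counterclockwise by polar angle around it,
    nearer points first on angle ties.  Collinear points are popped, so the
    result is the minimal vertex set, counterclockwise from the anchor.
    Degenerate inputs (all collinear) yield the two extreme endpoints.
    """
    pts = sorted({(int(p[0]), int(p[1])) for p in points})
    if len(pts) < 2:
        raise ValueError(f"need at least 2 distinct points, got {len(pts)}")
    anchor = min(pts, key=lambda p: (p[0], p[1]))
    rest = [p for p in pts if p != anchor]

    def polar(p):
        dx, dy = p[0] - anchor[0], p[1] - anchor[1]
        return (math.atan2(dy, dx), dx * dx + dy * dy)

    rest.sort(key=polar)
    stack: list[tuple[int, int]] = [anchor]
    for p in rest:
        while len(stack) >= 2 and cross_turn(stack[-2], stack[-1], p) <= 0:
            stack.pop()
        stack.append(p)
    return stack


def _bresenham(p0, p1):
    """Integer line rasterization between two (x, y) endpoints, inclusive."""
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = abs(x1 - x0), -abs(y1 - y0)
    sx = 1 if x0 < x1 else -1
    sy = 1 if y0 < y1 else -1
    err = dx + dy
    out = []
    while True:
        out.append((x0, y0))
        if (x0, y0) == (x1, y1):
            break
        e2 = 2 * err
        if e2 >= dy:
            err += dy
            x0 += sx
        if e2 <= dx:
            err += dx
            y0 += sy
    return out


def fill_polygon(hull, shape) -> np.ndarray:
    """Rasterize a convex polygon and fill its interior by scanlines.

    Consecutive hull edges are drawn with Bresenham's algorithm; each row
    is then filled between the leftmost and rightmost edge pixel, which is
    exact for convex polygons.  A 2-vertex hull degenerates to a line.
    """
    h, w = shape
    verts = [(int(p[0]), int(p[1])) for p in hull]
    if len(verts) < 2:
        raise ValueError("polygon needs at least 2 vertices")
    for x, y in verts:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"vertex ({x}, {y}) outside raster {shape}")
    out = np.zeros((h, w), dtype=np.uint8)
    edges = verts if len(verts) == 2 else verts + [verts[0]]
    span_lo = np.full(h, w, dtype=int)
    span_hi = np.full(h, -1, dtype=int)
    for p0, p1 in zip(edges[:-1], edges[1:]):
        for x, y in _bresenham(p0, p1):
            if x < span_lo[y]:
                span_lo[y] = x
            if x > span_hi[y]:
                span_hi[y] = x
    rows = np.nonzero(span_hi >= 0)[0]
    for y in rows:
        out[y, span_lo[y] : span_hi[y] + 1] = 1
    return out


def find_repair_regions(mask: np.ndarray, params: RepairParams | None = None):
    """Locate bridgeable gaps and collect their local point sets.

    For every pair of non-noise components whose minimal boundary-to-
    boundary Euclidean distance is at most ``max_gap_px``, the returned
    point set holds the boundary pixels of both components inside the
    window spanned by the two nearest boundary points (expanded by
    ``window_margin_px``), plus every pixel of noise-sized components
    inside that window.  Points are (x, y) tuples.
    """
    params = params or RepairParams()
    m = as_mask(mask)
    labels, count = connected_components(m, connectivity=8)
    if count < 1:
        return []
    areas = _component_areas(labels, count)
    big = [i for i in range(1, count + 1) if areas[i] >= params.min_fragment_px]
    noise = [i for i in range(1, count + 1) if areas[i] < params.min_fragment_px]
    if len(big) < 2 and not noise:
        return []

    bound = boundary_pixels(m)
    bpts = {}  # label -> (n, 2) array of (x, y)
    trees = {}
    for i in big:
        ys, xs = np.nonzero((labels == i) & (bound == 1))
        bpts[i] = np.column_stack([xs, ys])
        trees[i] = cKDTree(bpts[i])
    noise_pts = []
    for i in noise:
        ys, xs = np.nonzero(labels == i)
        noise_pts.append(np.column_stack([xs, ys]))
    noise_pts = np.vstack(noise_pts) if noise_pts else np.empty((0, 2), dtype=int)

    regions = []
    for i, j in combinations(big, 2):
        d, idx = trees[j].query(bpts[i], k=1, distance_upper_bound=params.max_gap_px + 1e-9)
        k = int(np.argmin(d))
        if not np.isfinite(d[k]) or d[k] > params.max_gap_px:
            continue
        pi = bpts[i][k].astype(float)
        pj = bpts[j][idx[k]].astype(float)
        gap = float(d[k])
        mgn = params.window_margin_px
        # Window aligned with the gap axis pi -> pj: a slab spanning the gap
        # (plus margin) along the axis and the full fragment cross-section
        # across it, so the filled hull meets both fragments flush instead
        # of leaving notches at the seams.
        u = (pj - pi) / max(gap, 1e-9)
        perp_limit = params.max_gap_px + mgn

        def in_window(pts, perp):
            if len(pts) == 0:
                return pts
            rel = pts - pi
            s = rel @ u
            t = rel @ np.array([-u[1], u[0]])
            keep = (s >= -mgn) & (s <= gap + mgn) & (np.abs(t) <= perp)
            return pts[keep]

        # Fragment boundaries may enter with their full cross-section;
        # noise points only from the narrow corridor between the fragments,
        # or hulling an outlying speck would bulge the repair.
        sel = [
            in_window(bpts[i], perp_limit),
            in_window(bpts[j], perp_limit),
            in_window(noise_pts, mgn),
        ]
        pts = np.vstack([s for s in sel if len(s)])
        if len(pts) >= 2:
            regions.append([(int(x), int(y)) for x, y in pts])
    return regions


def _component_areas(labels: np.ndarray, count: int) -> np.ndarray:
    """Pixel area per label, index 0 unused."""
    return np.bincount(labels.ravel(), minlength=count + 1)


def repair_mask(mask: np.ndarray, params: RepairParams | None = None) -> np.ndarray:
    """Union the filled gap hulls into the mask.

    The result is a superset of the input; bridged fragment pairs become
    8-connected, so the component count never increases.
    """
    params = params or RepairParams()
    m = as_mask(mask)
    out = m.copy()
    for region in find_repair_regions(m, params):
        hull = graham_hull(region)
        out = bitwise_or(out, fill_polygon(hull, m.shape))
    return out
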