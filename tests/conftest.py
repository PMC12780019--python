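"""Shared independent oracles for the geometry tests.

These are deliberately naive re-implementations (flood fill, O(n^3) hull,
exhaustive neighbour scan, all-pairs distance) kept separate from the
library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """8-connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = set()
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and \
                                    mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


def boundary_scan(mask: np.ndarray, pixels) -> set:
    """{foreground pixels with a background 4-neighbour or on the image edge}."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    out = set()
    for r, c in pixels:
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                out.add((int(r), int(c)))
                break
    return out


def _cross(o, u, v):
    return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])


def _on_segment(p, a, b) -> bool:
    return _cross(a, b, p) == 0 and \
        min(a[0], b[0]) <= p[0] <= max(a[0], b[0]) and \
        min(a[1], b[1]) <= p[1] <= max(a[1], b[1])


def _in_triangle(p, a, b, c) -> bool:
    """Inclusive point-in-triangle via consistent cross-product signs."""
    if _cross(a, b, c) == 0:      # degenerate: the triple is a segment
        lo, _, hi = sorted([a, b, c])
        return _on_segment(p, lo, hi)
    d1 = _cross(a, b, p)
    d2 = _cross(b, c, p)
    d3 = _cross(c, a, p)
    has_neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    has_pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (has_neg and has_pos)


def brute_force_hull_vertices(points) -> set:
    """Extreme points: keep p iff no triangle of three OTHER points contains it.

    O(n^4) in the worst case; intended for small n only.  Collinear inputs are
    reduced to the two lexicographic extremes.
    """
    pts = sorted({(float(r), float(c)) for r, c in points})
    if len(pts) <= 2:
        return set(pts)
    def cross(o, u, v):
        return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])
    if all(cross(pts[0], pts[-1], p) == 0 for p in pts):
        return {pts[0], pts[-1]}
    keep = set()
    for p in pts:
        others = [q for q in pts if q != p]
        contained = False
        n = len(others)
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    if _in_triangle(p, others[i], others[j], others[k]):
                        contained = True
                        break
                if contained:
                    break
            if contained:
                break
        if not contained:
            keep.add(p)
    return keep


def all_pairs_max_distance(points):
    """Exact maximum pairwise distance with the library's tie-break rule."""
    import math
    pts = [(float(r), float(c)) for r, c in points]
    best_d = -1.0
    best = None
    for i in range(len(pts)):
        for j in range(i, len(pts)):
            a, b = pts[i], pts[j]
            dr, dc = a[0] - b[0], a[1] - b[1]
            d = dr * dr + dc * dc
            pair = (a, b) if a <= b else (b, a)
            if d > best_d or (d == best_d and pair < best):
                best_d = d
                best = pair
    return math.sqrt(best_d), best


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
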