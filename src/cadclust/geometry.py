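"""Geometry on a 2D periodic rectangle.

All lengths are nanometres.  Points ("Vec2") are plain ``(x, y)`` pairs /
``ndarray``s of shape ``(2,)``.  The minimal-image convention places each
displacement component in the half-open interval ``[-L/2, L/2)``, so a tie at
exactly ``L/2`` resolves deterministically toward the negative bound.

Line segments are stored as an anchor ``a`` plus an endpoint ``b`` given
*unwrapped* relative to ``a``; this gives a segment a well-defined interior
even when it straddles the periodic boundary.  Segment-level operations
assume segment lengths below ``min(width, height) / 2`` so that minimal-image
re-centring of one segment against the other is unambiguous (longer actin
filaments are split into collinear pieces upstream, see
:mod:`cadclust.actin`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "PeriodicDomain",
    "LineSegment2",
    "wrap",
    "min_image_disp",
    "segments_cross",
    "point_segment_distance",
]


@dataclass(frozen=True)
class PeriodicDomain:
    """A periodic rectangle ``[0, width) x [0, height)`` in nm."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and math.isfinite(self.width)):
            raise ValueError(f"domain width must be positive and finite, got {self.width}")
        if not (self.height > 0 and math.isfinite(self.height)):
            raise ValueError(f"domain height must be positive and finite, got {self.height}")

    @property
    def min_dim(self) -> float:
        return min(self.width, self.height)

    @property
    def area_um2(self) -> float:
        return self.width * self.height * 1e-6


@dataclass(frozen=True)
class LineSegment2:
    """Segment from ``a`` to ``b``, with ``b`` unwrapped relative to ``a``."""

    ax: float
    ay: float
    bx: float
    by: float

    @classmethod
    def from_points(cls, a, b) -> "LineSegment2":
        return cls(float(a[0]), float(a[1]), float(b[0]), float(b[1]))

    @property
    def a(self) -> np.ndarray:
        return np.array([self.ax, self.ay])

    @property
    def b(self) -> np.ndarray:
        return np.array([self.bx, self.by])

    @property
    def length(self) -> float:
        return math.hypot(self.bx - self.ax, self.by - self.ay)


# ---------------------------------------------------------------------------
# numba primitives (shared with the simulation kernel)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _wrap1(x, L):
    r = x % L
    if r >= L:  # guard against float rounding at the boundary
        r -= L
    elif r < 0.0:
        r += L
    return r


@njit(cache=True)
def _mi1(d, L):
    """Minimal-image difference, in [-L/2, L/2)."""
    return d - L * math.floor(d / L + 0.5)


@njit(cache=True)
def _on_seg(px, py, qx, qy, rx, ry):
    # r known collinear with p-q: is it inside the bounding box?
    return (
        min(px, qx) - 1e-12 <= rx <= max(px, qx) + 1e-12
        and min(py, qy) - 1e-12 <= ry <= max(py, qy) + 1e-12
    )


@njit(cache=True)
def _orient(px, py, qx, qy, rx, ry):
    v = (qx - px) * (ry - py) - (qy - py) * (rx - px)
    if v > 0.0:
        return 1
    if v < 0.0:
        return -1
    return 0


@njit(cache=True)
def _seg_int_plain(p0x, p0y, p1x, p1y, q0x, q0y, q1x, q1y):
    """Non-periodic segment intersection; touching endpoints count."""
    d1 = _orient(q0x, q0y, q1x, q1y, p0x, p0y)
    d2 = _orient(q0x, q0y, q1x, q1y, p1x, p1y)
    d3 = _orient(p0x, p0y, p1x, p1y, q0x, q0y)
    d4 = _orient(p0x, p0y, p1x, p1y, q1x, q1y)
    if ((d1 > 0 and d2 < 0) or (d1 < 0 and d2 > 0)) and (
        (d3 > 0 and d4 < 0) or (d3 < 0 and d4 > 0)
    ):
        return True
    if d1 == 0 and _on_seg(q0x, q0y, q1x, q1y, p0x, p0y):
        return True
    if d2 == 0 and _on_seg(q0x, q0y, q1x, q1y, p1x, p1y):
        return True
    if d3 == 0 and _on_seg(p0x, p0y, p1x, p1y, q0x, q0y):
        return True
    if d4 == 0 and _on_seg(p0x, p0y, p1x, p1y, q1x, q1y):
        return True
    return False


@njit(cache=True)
def _segments_cross(p0x, p0y, pdx, pdy, q0x, q0y, qdx, qdy, W, H):
    """Periodic intersection test; segments given as anchor + unwrapped delta.

    Re-centres the second segment so its midpoint sits at the minimal-image
    position relative to the first segment's midpoint.  Valid whenever both
    lengths are below ``min(W, H) / 2``.
    """
    pmx = p0x + 0.5 * pdx
    pmy = p0y + 0.5 * pdy
    qmx = q0x + 0.5 * qdx
    qmy = q0y + 0.5 * qdy
    rx = _mi1(qmx - pmx, W)
    ry = _mi1(qmy - pmy, H)
    sx = pmx + rx - 0.5 * qdx
    sy = pmy + ry - 0.5 * qdy
    return _seg_int_plain(p0x, p0y, p0x + pdx, p0y + pdy, sx, sy, sx + qdx, sy + qdy)


@njit(cache=True)
def _point_seg_dist(px, py, ax, ay, dx, dy, W, H):
    """Periodic distance from point to segment (anchor + unwrapped delta)."""
    mx = ax + 0.5 * dx
    my = ay + 0.5 * dy
    rx = _mi1(px - mx, W)
    ry = _mi1(py - my, H)
    # point position relative to the anchor, in the re-centred frame
    vx = 0.5 * dx + rx
    vy = 0.5 * dy + ry
    L2 = dx * dx + dy * dy
    if L2 > 0.0:
        t = (vx * dx + vy * dy) / L2
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
    else:
        t = 0.0
    ex = vx - t * dx
    ey = vy - t * dy
    return math.sqrt(ex * ex + ey * ey)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def wrap(p, dom: PeriodicDomain) -> np.ndarray:
    """Wrap a point into ``[0, width) x [0, height)``."""
    return np.array([_wrap1(float(p[0]), dom.width), _wrap1(float(p[1]), dom.height)])


def min_image_disp(a, b, dom: PeriodicDomain) -> np.ndarray:
    """Shortest periodic displacement a -> b, components in [-L/2, L/2)."""
    return np.array(
        [
            _mi1(float(b[0]) - float(a[0]), dom.width),
            _mi1(float(b[1]) - float(a[1]), dom.height),
        ]
    )


def segments_cross(path: LineSegment2, obstacle: LineSegment2, dom: PeriodicDomain) -> bool:
    """True iff the segments intersect under the minimal-image convention.

    A shared single point (endpoint touch) counts as an intersection; the
    engine uses this conservatively to reject moves that graze a filament.
    """
    return bool(
        _segments_cross(
            path.ax,
            path.ay,
            path.bx - path.ax,
            path.by - path.ay,
            obstacle.ax,
            obstacle.ay,
            obstacle.bx - obstacle.ax,
            obstacle.by - obstacle.ay,
            dom.width,
            dom.height,
        )
    )


def point_segment_distance(p, s: LineSegment2, dom: PeriodicDomain) -> float:
    """Minimal-image Euclidean distance from ``p`` to the nearest point of ``s``."""
    return float(
        _point_seg_dist(
            float(p[0]),
            float(p[1]),
            s.ax,
            s.ay,
            s.bx - s.ax,
            s.by - s.ay,
            dom.width,
            dom.height,
        )
    )
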