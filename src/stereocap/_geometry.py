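"""Exact 2D geometry for elliptical capillary profiles and test probes.

Every predicate here is evaluated analytically: an ellipse is mapped by the
affine transform that sends it to the unit circle, and the probe element
(point, segment, rectangle edge) is tested against the circle in that frame.
Affine maps preserve incidence and tangency, so the counting decisions are
exact up to floating point -- no polygonal approximation is involved.

All functions are vectorised over ellipses. An ellipse set is given by five
equal-length arrays: centre coordinates ``cx, cy``, semi-axes ``a >= b > 0``
(``a`` along the major axis) and the major-axis angle ``theta`` (radians,
counter-clockwise from +x).
"""

from __future__ import annotations

import numpy as np

Rect = tuple[float, float, float, float]  # (x0, y0, x1, y1), x0 < x1, y0 < y1


def _to_circle_frame(
    px: np.ndarray,
    py: np.ndarray,
    cx: np.ndarray,
    cy: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    theta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Map points into the frame where each ellipse is the unit circle.

    Broadcasts ``(px, py)`` against the ellipse arrays.
    """
    dx = px - cx
    dy = py - cy
    ct = np.cos(theta)
    st = np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    return u, v


def points_in_ellipses(
    points: np.ndarray,
    cx: np.ndarray,
    cy: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    theta: np.ndarray,
    strict: bool = True,
) -> np.ndarray:
    """Membership matrix of shape (n_points, n_ellipses).

    ``strict`` tests the open interior (the counting rule for grid points);
    otherwise the closed ellipse.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u, v = _to_circle_frame(
        pts[:, 0:1], pts[:, 1:2], cx[None, :], cy[None, :], a[None, :], b[None, :], theta[None, :]
    )
    r2 = u * u + v * v
    return r2 < 1.0 if strict else r2 <= 1.0


def _segment_min_dist2(qx0, qy0, qx1, qy1):
    """Squared distance from the origin to segments (vectorised)."""
    vx = qx1 - qx0
    vy = qy1 - qy0
    vv = vx * vx + vy * vy
    # Degenerate segment (zero length in circle frame) falls back to endpoint.
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(vv > 0, -(qx0 * vx + qy0 * vy) / np.where(vv > 0, vv, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    px = qx0 + t * vx
    py = qy0 + t * vy
    return px * px + py * py


def segments_touch_ellipses(
    p0: np.ndarray,
    p1: np.ndarray,
    cx: np.ndarray,
    cy: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    theta: np.ndarray,
) -> np.ndarray:
    """Whether the closed segment p0-p1 meets each closed ellipse.

    True when the segment crosses, touches, or lies inside the ellipse.
    """
    q0u, q0v = _to_circle_frame(p0[0], p0[1], cx, cy, a, b, theta)
    q1u, q1v = _to_circle_frame(p1[0], p1[1], cx, cy, a, b, theta)
    return _segment_min_dist2(q0u, q0v, q1u, q1v) <= 1.0


def segment_boundary_crossings(
    p0: np.ndarray,
    p1: np.ndarray,
    cx: np.ndarray,
    cy: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    theta: np.ndarray,
    rel_eps: float = 1e-12,
) -> np.ndarray:
    """Number of intersections of segment p0-p1 with each ellipse *boundary*.

    A transversal pass through the ellipse counts 2, a tangency counts 1, a
    chord endpoint inside counts 1, a segment wholly inside counts 0.  This is
    the intersection-counting rule used with stereological test lines.
    """
    q0u, q0v = _to_circle_frame(p0[0], p0[1], cx, cy, a, b, theta)
    q1u, q1v = _to_circle_frame(p1[0], p1[1], cx, cy, a, b, theta)
    vx = q1u - q0u
    vy = q1v - q0v
    A = vx * vx + vy * vy
    B = 2.0 * (q0u * vx + q0v * vy)
    C = q0u * q0u + q0v * q0v - 1.0
    disc = B * B - 4.0 * A * C
    counts = np.zeros(np.shape(A), dtype=np.int64)
    scale = np.maximum(B * B, np.abs(4.0 * A * C)) + 1e-300
    tangent = np.abs(disc) <= rel_eps * scale
    crossing = (disc > 0) & ~tangent & (A > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        sq = np.sqrt(np.where(disc > 0, disc, 0.0))
        t1 = np.where(A > 0, (-B - sq) / (2.0 * np.where(A > 0, A, 1.0)), np.nan)
        t2 = np.where(A > 0, (-B + sq) / (2.0 * np.where(A > 0, A, 1.0)), np.nan)
        t0 = np.where(A > 0, -B / (2.0 * np.where(A > 0, A, 1.0)), np.nan)
    in01 = lambda t: (t >= 0.0) & (t <= 1.0)  # noqa: E731
    counts += np.where(crossing & in01(t1), 1, 0)
    counts += np.where(crossing & in01(t2), 1, 0)
    counts += np.where(tangent & (A > 0) & in01(t0), 1, 0)
    return counts


def point_in_rect(px: float, py: float, rect: Rect) -> bool:
    x0, y0, x1, y1 = rect
    return (x0 <= px <= x1) and (y0 <= py <= y1)


def ellipses_touch_rect(
    rect: Rect,
    cx: np.ndarray,
    cy: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    theta: np.ndarray,
) -> np.ndarray:
    """Whether each ellipse meets the closed rectangle.

    True iff the ellipse centre lies in the rectangle or the ellipse meets
    one of the four edges (covers all overlap configurations: partial
    overlap, rectangle inside ellipse, ellipse inside rectangle).
    """
    x0, y0, x1, y1 = rect
    inside = (cx >= x0) & (cx <= x1) & (cy >= y0) & (cy <= y1)
    edges = (
        (np.array([x0, y0]), np.array([x1, y0])),
        (np.array([x1, y0]), np.array([x1, y1])),
        (np.array([x1, y1]), np.array([x0, y1])),
        (np.array([x0, y1]), np.array([x0, y0])),
    )
    touch = inside
    for p0, p1 in edges:
        touch = touch | segments_touch_ellipses(p0, p1, cx, cy, a, b, theta)
    return touch


def clip_segment_to_rect(
    p0: np.ndarray, p1: np.ndarray, rect: Rect
) -> tuple[np.ndarray, np.ndarray] | None:
    """Liang-Barsky clip of segment p0-p1 to an axis-aligned rectangle.

    Returns the clipped endpoints, or None when the segment misses the
    rectangle entirely.
    """
    x0, y0, x1, y1 = rect
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-d[0], p0[0] - x0),
        (d[0], x1 - p0[0]),
        (-d[1], p0[1] - y0),
        (d[1], y1 - p0[1]),
    ):
        if p == 0.0:
            if q < 0.0:
                return None
            continue
        r = q / p
        if p < 0.0:
            if r > t1:
                return None
            t0 = max(t0, r)
        else:
            if r < t0:
                return None
            t1 = min(t1, r)
    if t0 > t1:
        return None
    return p0 + t0 * d, p0 + t1 * d


def ellipse_area(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.pi * a * b


def ellipse_perimeter(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact ellipse perimeter via the complete elliptic integral E(m)."""
    from scipy.special import ellipe

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = 1.0 - (b / a) ** 2
    return 4.0 * a * ellipe(m)
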