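"""Compiled geometry kernels: point-in-polygon, line of sight, wall queries,
collision resolution.

Walls are passed as two ``(S, 2)`` float64 arrays of segment endpoints
(``seg_a[s] -> seg_b[s]``), the concatenation of every ring (outer boundary
plus holes) of an arena. All kernels are numba-compiled with on-disk caching
so that repeated processes (tests, sweeps) pay the compile cost once.
"""

import numba as nb
import numpy as np

__all__ = [
    "points_inside",
    "los_clear",
    "pair_visibility",
    "cross_visibility",
    "wall_query_batch",
    "resolve_collisions",
]


@nb.njit(cache=True, inline="always")
def _orient(px, py, qx, qy, rx, ry):
    # twice the signed area of triangle (p, q, r)
    return (qx - px) * (ry - py) - (qy - py) * (rx - px)


@nb.njit(cache=True, inline="always")
def _pt_seg_d2(px, py, ax, ay, bx, by):
    """Squared distance from point to segment, plus the nearest point."""
    vx = bx - ax
    vy = by - ay
    wx = px - ax
    wy = py - ay
    vv = vx * vx + vy * vy
    if vv > 0.0:
        t = (wx * vx + wy * vy) / vv
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
    else:
        t = 0.0
    nx = ax + t * vx
    ny = ay + t * vy
    dx = px - nx
    dy = py - ny
    return dx * dx + dy * dy, nx, ny


@nb.njit(cache=True)
def _inside_mind2(px, py, seg_a, seg_b):
    """Even-odd crossing parity over all rings and min squared wall distance."""
    inside = False
    mind2 = np.inf
    for s in range(seg_a.shape[0]):
        x1 = seg_a[s, 0]
        y1 = seg_a[s, 1]
        x2 = seg_b[s, 0]
        y2 = seg_b[s, 1]
        if (y1 > py) != (y2 > py):
            xin = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if xin > px:
                inside = not inside
        d2, _, _ = _pt_seg_d2(px, py, x1, y1, x2, y2)
        if d2 < mind2:
            mind2 = d2
    return inside, mind2


@nb.njit(cache=True)
def points_inside(P, seg_a, seg_b):
    """Allowability mask: inside by even-odd rule and strictly off every wall."""
    n = P.shape[0]
    out = np.empty(n, np.bool_)
    for i in range(n):
        inside, mind2 = _inside_mind2(P[i, 0], P[i, 1], seg_a, seg_b)
        out[i] = inside and mind2 > 0.0
    return out


@nb.njit(cache=True)
def los_clear(ax, ay, bx, by, seg_a, seg_b, eps):
    """True iff the open segment (a, b), shrunk inward by eps at both ends,
    properly crosses no wall segment."""
    dx = bx - ax
    dy = by - ay
    length = np.sqrt(dx * dx + dy * dy)
    if length <= 2.0 * eps:
        return True
    ux = dx / length
    uy = dy / length
    ax2 = ax + eps * ux
    ay2 = ay + eps * uy
    bx2 = bx - eps * ux
    by2 = by - eps * uy
    for s in range(seg_a.shape[0]):
        wax = seg_a[s, 0]
        way = seg_a[s, 1]
        wbx = seg_b[s, 0]
        wby = seg_b[s, 1]
        d1 = _orient(ax2, ay2, bx2, by2, wax, way)
        d2 = _orient(ax2, ay2, bx2, by2, wbx, wby)
        if d1 * d2 >= 0.0:
            continue
        d3 = _orient(wax, way, wbx, wby, ax2, ay2)
        d4 = _orient(wax, way, wbx, wby, bx2, by2)
        if d3 * d4 < 0.0:
            return False
    return True


@nb.njit(cache=True)
def pair_visibility(P, seg_a, seg_b, d_max, eps):
    """Symmetric visibility (range + line of sight) and distance matrices."""
    n = P.shape[0]
    V = np.zeros((n, n))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dx = P[j, 0] - P[i, 0]
            dy = P[j, 1] - P[i, 1]
            d = np.sqrt(dx * dx + dy * dy)
            D[i, j] = d
            D[j, i] = d
            if d <= d_max and los_clear(
                P[i, 0], P[i, 1], P[j, 0], P[j, 1], seg_a, seg_b, eps
            ):
                V[i, j] = 1.0
                V[j, i] = 1.0
    return V, D


@nb.njit(cache=True)
def cross_visibility(P, Q, seg_a, seg_b, eps):
    """Line-of-sight-only visibility and distances from points P to targets Q."""
    n = P.shape[0]
    k = Q.shape[0]
    V = np.zeros((n, k))
    D = np.zeros((n, k))
    for i in range(n):
        for j in range(k):
            dx = Q[j, 0] - P[i, 0]
            dy = Q[j, 1] - P[i, 1]
            D[i, j] = np.sqrt(dx * dx + dy * dy)
            if los_clear(P[i, 0], P[i, 1], Q[j, 0], Q[j, 1], seg_a, seg_b, eps):
                V[i, j] = 1.0
    return V, D


@nb.njit(cache=True)
def wall_query_batch(P, seg_a, seg_b):
    """Distance to the nearest wall and the unit normal pointing back toward
    each query point. Ties go to the lowest segment index (strict < scan)."""
    n = P.shape[0]
    dist = np.empty(n)
    normal = np.zeros((n, 2))
    for i in range(n):
        px = P[i, 0]
        py = P[i, 1]
        best = np.inf
        bx = 0.0
        by = 0.0
        for s in range(seg_a.shape[0]):
            d2, nx, ny = _pt_seg_d2(
                px, py, seg_a[s, 0], seg_a[s, 1], seg_b[s, 0], seg_b[s, 1]
            )
            if d2 < best:
                best = d2
                bx = nx
                by = ny
        d = np.sqrt(best)
        dist[i] = d
        if d > 0.0:
            normal[i, 0] = (px - bx) / d
            normal[i, 1] = (py - by) / d
    return dist, normal


@nb.njit(cache=True)
def resolve_collisions(X0, X1, VEL, seg_a, seg_b, retract):
    """Stop motion segments at their first wall crossing.

    Each row moves from allowable ``X0[i]`` toward ``X1[i]``. If the segment
    crosses a wall, the point stops at the crossing retracted by ``retract``
    along the incoming direction and the wall-normal component of ``VEL[i]``
    is zeroed. Any resulting point that is still not allowable (e.g. corner
    degeneracies) reverts to ``X0[i]``.
    """
    n = X0.shape[0]
    Xo = X1.copy()
    Vo = VEL.copy()
    for i in range(n):
        ax = X0[i, 0]
        ay = X0[i, 1]
        bx = X1[i, 0]
        by = X1[i, 1]
        rx = bx - ax
        ry = by - ay
        if rx == 0.0 and ry == 0.0:
            continue
        tmin = 2.0
        smin = -1
        for s in range(seg_a.shape[0]):
            qx = seg_a[s, 0]
            qy = seg_a[s, 1]
            sx = seg_b[s, 0] - qx
            sy = seg_b[s, 1] - qy
            den = rx * sy - ry * sx
            if den == 0.0:
                continue
            qpx = qx - ax
            qpy = qy - ay
            t = (qpx * sy - qpy * sx) / den
            u = (qpx * ry - qpy * rx) / den
            if 0.0 < t <= 1.0 and 0.0 <= u <= 1.0 and t < tmin:
                tmin = t
                smin = s
        if smin >= 0:
            length = np.sqrt(rx * rx + ry * ry)
            t2 = tmin - retract / length
            if t2 < 0.0:
                t2 = 0.0
            Xo[i, 0] = ax + t2 * rx
            Xo[i, 1] = ay + t2 * ry
            # zero the velocity component normal to the crossed wall
            sx = seg_b[smin, 0] - seg_a[smin, 0]
            sy = seg_b[smin, 1] - seg_a[smin, 1]
            slen = np.sqrt(sx * sx + sy * sy)
            if slen > 0.0:
                nx = -sy / slen
                ny = sx / slen
                vn = Vo[i, 0] * nx + Vo[i, 1] * ny
                Vo[i, 0] -= vn * nx
                Vo[i, 1] -= vn * ny
        inside, mind2 = _inside_mind2(Xo[i, 0], Xo[i, 1], seg_a, seg_b)
        if (not inside) or mind2 <= 0.0:
            Xo[i, 0] = ax
            Xo[i, 1] = ay
    return Xo, Vo
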