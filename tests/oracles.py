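"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with elementary math (pure
Python loops, ray casting, normal equations) and stays independent of
the package's implementation paths.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# geometry primitives (no shapely)


def point_segment_distance(px, py, ax, ay, bx, by) -> float:
    dx, dy = bx - ax, by - ay
    if dx == 0 and dy == 0:
        return math.hypot(px - ax, py - ay)
    t = ((px - ax) * dx + (py - ay) * dy) / (dx * dx + dy * dy)
    t = max(0.0, min(1.0, t))
    return math.hypot(px - (ax + t * dx), py - (ay + t * dy))


def ring_segments(coords):
    return [
        (coords[i][0], coords[i][1], coords[i + 1][0], coords[i + 1][1])
        for i in range(len(coords) - 1)
    ]


def point_in_ring(px, py, coords) -> bool:
    """Even-odd ray casting against a closed coordinate ring."""
    inside = False
    n = len(coords) - 1
    for i in range(n):
        x1, y1 = coords[i]
        x2, y2 = coords[i + 1]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def geometry_distance(px, py, geom) -> float:
    """Distance from a point to a shapely geometry, recomputed from its
    raw coordinates with elementary math (0 inside polygons)."""
    gtype = geom.geom_type
    if gtype == "Point":
        return math.hypot(px - geom.x, py - geom.y)
    if gtype == "LineString":
        return min(
            point_segment_distance(px, py, *seg)
            for seg in ring_segments(list(geom.coords))
        )
    if gtype == "Polygon":
        exterior = list(geom.exterior.coords)
        if point_in_ring(px, py, exterior):
            for hole in geom.interiors:
                if point_in_ring(px, py, list(hole.coords)):
                    return min(
                        point_segment_distance(px, py, *seg)
                        for seg in ring_segments(list(hole.coords))
                    )
            return 0.0
        d = min(
            point_segment_distance(px, py, *seg) for seg in ring_segments(exterior)
        )
        for hole in geom.interiors:
            d = min(
                d,
                min(
                    point_segment_distance(px, py, *seg)
                    for seg in ring_segments(list(hole.coords))
                ),
            )
        return d
    if gtype.startswith("Multi") or gtype == "GeometryCollection":
        return min(geometry_distance(px, py, g) for g in geom.geoms)
    raise NotImplementedError(gtype)


def point_in_geometry(px, py, geom) -> bool:
    """Ray-casting point-in-polygon (boundary treatment: even-odd rule)."""
    if geom.geom_type == "Polygon":
        if not point_in_ring(px, py, list(geom.exterior.coords)):
            return False
        return not any(
            point_in_ring(px, py, list(h.coords)) for h in geom.interiors
        )
    if geom.geom_type == "MultiPolygon":
        return any(point_in_geometry(px, py, g) for g in geom.geoms)
    raise NotImplementedError(geom.geom_type)


# ---------------------------------------------------------------------------
# threat-surface brute force


def oracle_magnitude(feature, spec, pool_attrs) -> float:
    if spec.magnitude_rule == "fixed":
        return spec.magnitude
    lo, hi = spec.magnitude_range
    amin, amax = min(pool_attrs), max(pool_attrs)
    if amax == amin:
        return hi
    return lo + (feature.attribute - amin) / (amax - amin) * (hi - lo)


def oracle_distance(spec) -> float:
    if spec.distance_rule == "fixed":
        return spec.impact_distance_m
    return min(
        spec.impact_distance_m,
        spec.impact_distance_m * spec.magnitude / spec.distance_scale_reference,
    )


def brute_force_surface(features, registry, grid, policy="cap") -> np.ndarray:
    """Per-pixel, per-feature loop re-deriving the impact surface."""
    pools: dict[str, list[float]] = {}
    for f in features:
        if registry[f.key].magnitude_rule == "attribute_scaled":
            pools.setdefault(f.threat, []).append(f.attribute)
    xs = grid.x_centers()
    ys = grid.y_centers()
    values = np.zeros(grid.shape)
    for r in range(grid.nrows):
        for c in range(grid.ncols):
            total = 0.0
            for f in features:
                spec = registry[f.key]
                m = oracle_magnitude(f, spec, pools.get(f.threat, []))
                dmax = oracle_distance(spec)
                d = geometry_distance(xs[c], ys[r], f.geometry)
                if d < dmax:
                    total += m * (1.0 - d / dmax)
            values[r, c] = total
    if policy == "cap":
        return np.minimum(values, 1.0)
    peak = values.max()
    return values / peak if peak > 1 else values


# ---------------------------------------------------------------------------
# statistics


def normal_equations(y, X) -> np.ndarray:
    """Textbook (X'X)^-1 X'y with an explicit intercept column prepended."""
    Xd = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)


def gaussian_loglik(y, X) -> float:
    beta = normal_equations(y, X)
    resid = y - np.column_stack([np.ones(len(y)), X]) @ beta
    n = len(y)
    s2 = float(resid @ resid) / n
    return -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)


def textbook_aicc(loglik, n, k) -> float:
    return -2 * loglik + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


def brute_force_moran(values, W) -> float:
    """Double-sum Moran's I."""
    x = np.asarray(values, dtype=float)
    n = x.size
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += W[i, j]
    den = float(np.sum((x - xbar) ** 2))
    return (n / s0) * num / den


def pearson_r2(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ca = a - a.mean()
    cb = b - b.mean()
    return float((ca @ cb) ** 2 / ((ca @ ca) * (cb @ cb)))
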