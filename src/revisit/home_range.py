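"""Local-convex-hull home range and availability sampling.

The home range is a union of local convex hulls: for every point a local
set of nearest neighbours is formed, its convex hull taken, and the hulls
are unioned in ascending area order until the union contains the requested
isopleth fraction of points.  Two neighbour rules are provided:

* ``"radius"`` (default): include every neighbour within distance ``a`` of
  the root.  With ``a`` set to the maximum observed pairwise distance every
  local set contains all points, so at isopleth 1 the estimate collapses to
  the global convex hull — the parameterisation used when the home range
  should encompass 100% of the data.
* ``"cumulative"``: the adaptive rule — neighbours are added in order of
  increasing distance while the running sum of distances stays at or below
  ``a``; this adapts hull size to local point density.

Availability is modelled as complete spatial randomness: points sampled
uniformly in the home range with buffered water removed, each stamped with
an entry time drawn from the observed visit entry times so that dynamic
covariates can be extracted for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree, ConvexHull
from shapely.geometry import MultiPoint, Polygon

logger = logging.getLogger(__name__)

__all__ = ["HomeRange", "alocoh", "default_a", "sample_available", "AvailablePoint"]


@dataclass
class HomeRange:
    polygon: shapely.Geometry
    a_value: float
    isopleth: float

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass(frozen=True)
class AvailablePoint:
    x: float
    y: float
    stamped_time: float  # epoch seconds, drawn from observed entry times


def default_a(points: np.ndarray) -> float:
    """Maximum pairwise distance among points.

    Exact all-pairs computation up to 10^4 points; above that the maximum
    is found among convex-hull vertices only (the diameter of a point set
    is attained on its hull), which is exact and far cheaper.
    """
    pts = np.asarray(points, float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    if len(pts) > 10_000:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear input: fall through to all-pairs on raw points
            pass
    best = 0.0
    for i0 in range(0, len(pts), 1024):
        chunk = pts[i0:i0 + 1024]
        d2 = np.sum((chunk[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        best = max(best, float(d2.max()))
    return float(np.sqrt(best))


def alocoh(points: np.ndarray, a: float | None = None, isopleth: float = 1.0,
           rule: str = "radius") -> HomeRange:
    """Local-convex-hull home range at the given isopleth level.

    Parameters
    ----------
    points : (n, 2) array of projected coordinates, metres
    a : neighbour-rule parameter in metres; default :func:`default_a`
    isopleth : fraction of points the polygon must contain, in (0, 1]
    rule : "radius" or "cumulative" neighbour rule (see module docstring)
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 (x, y) points")
    if not 0.0 < isopleth <= 1.0:
        raise ValueError("isopleth must be in (0, 1]")
    if a is None:
        a = default_a(pts)
    if a <= 0:
        raise ValueError("a must be positive")
    if rule not in ("radius", "cumulative"):
        raise ValueError(f"unknown neighbour rule {rule!r}")

    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3 or _collinear(uniq):
        raise ValueError("degenerate geometry: points are collinear or fewer than 3 distinct")

    # radius rule with a >= diameter: every local set is the full point set
    if rule == "radius" and a >= default_a(uniq):
        hull = MultiPoint(uniq).convex_hull
        return HomeRange(hull, float(a), isopleth)

    tree = cKDTree(uniq)
    hulls = []
    for root in uniq:
        if rule == "radius":
            idx = tree.query_ball_point(root, r=a)
            local = uniq[idx]
        else:
            d, idx = tree.query(root, k=len(uniq))
            d = np.atleast_1d(d)
            idx = np.atleast_1d(idx)
            keep = np.cumsum(d) <= a
            keep[0] = True  # the root itself (distance 0) is always in
            local = uniq[idx[keep]]
        geom = MultiPoint(local).convex_hull  # point/line for <3 non-collinear
        if geom.area > 0 or len(local) >= 1:
            hulls.append(geom)

    hulls.sort(key=lambda g: g.area)
    n = len(pts)
    target = isopleth * n
    union = None
    pt_geoms = shapely.points(pts[:, 0], pts[:, 1])
    for k, h in enumerate(hulls, 1):
        union = h if union is None else shapely.union_all([union, h])
        covered = int(np.count_nonzero(shapely.covers(union, pt_geoms)))
        if covered >= target:
            break
    if union is None or union.area == 0:
        raise ValueError("degenerate geometry: hull union has zero area")
    logger.info("home range: %d hulls, area %.3g m^2, isopleth %.2f", k, union.area, isopleth)
    return HomeRange(union, float(a), isopleth)


def _collinear(pts: np.ndarray) -> bool:
    p0 = pts[0]
    v = pts[1:] - p0
    cross = v[:, 0, None] * v[None, :, 1] - v[:, 1, None] * v[None, :, 0]
    return bool(np.allclose(cross, 0.0))


def sample_available(hr: HomeRange, water, buffer: float, n: int,
                     entry_times: np.ndarray, seed) -> list[AvailablePoint]:
    """CSR (uniform) points in the home range outside buffered water.

    Rejection-samples uniformly in the bounding box of the sampling region
    (home-range polygon minus water buffered by ``buffer``) until ``n``
    points are accepted, then stamps each with an entry time drawn with
    replacement from the observed visit entry times.  Fully reproducible
    for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    entry_times = np.asarray(entry_times, float)
    if len(entry_times) == 0:
        raise ValueError("need at least one entry time to stamp")
    region = hr.polygon
    if water is not None and not water.is_empty() and buffer >= 0:
        region = region.difference(water.buffered(buffer))
    if region.is_empty:
        raise ValueError("region nearly empty: home range minus buffered water is empty")
    minx, miny, maxx, maxy = region.bounds
    rng = np.random.default_rng(seed)
    xs = np.empty(0)
    ys = np.empty(0)
    tried = 0
    accepted = 0
    batch = max(4 * n, 1000)
    while accepted < n:
        cx = rng.uniform(minx, maxx, batch)
        cy = rng.uniform(miny, maxy, batch)
        inside = shapely.covers(region, shapely.points(cx, cy))
        tried += batch
        xs = np.concatenate([xs, cx[inside]])
        ys = np.concatenate([ys, cy[inside]])
        accepted = len(xs)
        if tried >= 10 * batch and accepted / tried < 1e-4:
            raise ValueError("region nearly empty: acceptance rate below 1e-4")
    xs, ys = xs[:n], ys[:n]
    stamps = rng.choice(entry_times, size=n, replace=True)
    return [AvailablePoint(float(x), float(y), float(t)) for x, y, t in zip(xs, ys, stamps)]
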