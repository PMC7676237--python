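"""Surrogate modelling for adaptive acquisition.

The surrogate is a scattered-data linear interpolator: a Delaunay
triangulation of the sampled positions with barycentric interpolation inside
each triangle, applied to each value dimension (PCA score or spectral channel)
independently.  Outside the convex hull of the support points the surrogate
falls back to the value of the nearest support point, which keeps evaluation
defined everywhere in the rectangular map domain.

Around the interpolator this module provides:

* boundary-clipped Voronoi tessellation with finite cell areas, the sampler's
  proxy for local sampling sparsity;
* leave-one-out (LOO) errors — for each sampled point, the L2 discrepancy at
  that point between the full surrogate and the surrogate rebuilt without it;
* the min-max normalization used to bring LOO errors and Voronoi areas onto a
  common [0, 1] scale;
* the regularized error  e_i = sigma(eps_LOO_i) + sigma(V_i)  that drives the
  LIV strategy, and the Voronoi-area-weighted mean LOO error used to track
  model accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError, Voronoi, cKDTree

from .spectral_io import DomainRect

__all__ = [
    "SurrogateModel",
    "VoronoiPartition",
    "ErrorTable",
    "build_model",
    "voronoi_partition",
    "loo_errors",
    "normalize_minmax",
    "regularized_errors",
    "mean_weighted_loo",
]


class SurrogateModel:
    """Piecewise-linear interpolator over scattered support points.

    ``values`` may be multi-dimensional: shape (n_points, n_values).  Inside
    the convex hull of the support a query returns the barycentric combination
    of the containing triangle's vertex values; outside the hull it returns
    the nearest support point's values.
    """

    def __init__(self, points: np.ndarray, values: np.ndarray, domain: DomainRect):
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if points.shape[0] < 3:
            raise ValueError("degenerate support: need at least 3 points")
        if not np.all(domain.contains(points)):
            raise ValueError("out of domain: support points outside the domain")
        try:
            self._interp = LinearNDInterpolator(points, values)
        except QhullError as exc:
            raise ValueError("degenerate support: points are collinear") from exc
        if self._interp.tri.nsimplex == 0:
            raise ValueError("degenerate support: points are collinear")
        self.points = points
        self.values = values
        self.domain = domain
        self._tree = cKDTree(points)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_values(self) -> int:
        return self.values.shape[1]

    def __call__(self, queries: np.ndarray) -> np.ndarray:
        return evaluate(self, queries)


def build_model(
    points: np.ndarray, values: np.ndarray, domain: DomainRect
) -> SurrogateModel:
    """Build a per-dimension barycentric linear interpolation model."""
    return SurrogateModel(points, values, domain)


def evaluate(model: SurrogateModel, queries: np.ndarray) -> np.ndarray:
    """Evaluate a model at an (n, 2) batch of query points.

    Queries outside the support's convex hull use the nearest-support-point
    fallback; queries outside the map domain raise.
    """
    queries = np.asarray(queries, dtype=float).reshape(-1, 2)
    if not np.all(model.domain.contains(queries)):
        raise ValueError("out of domain: query outside the map domain")
    out = model._interp(queries)
    bad = np.any(np.isnan(out), axis=1)
    if np.any(bad):
        _, nearest = model._tree.query(queries[bad])
        out[bad] = model.values[nearest]
    return out


@dataclass
class VoronoiPartition:
    """Boundary-clipped Voronoi cells of the sampled points.

    ``cells[i]`` is the polygon (counter-clockwise (k, 2) vertex array) of the
    region of the domain rectangle closer to ``points[i]`` than to any other
    point; ``areas[i]`` its area in um^2.  The cells partition the domain, so
    the areas sum to the domain area.
    """

    points: np.ndarray
    cells: list[np.ndarray]
    areas: np.ndarray
    domain: DomainRect

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _clip_halfplane(
    vertices: np.ndarray, a: float, b: float, c: float
) -> np.ndarray:
    """Sutherland-Hodgman clip of a convex polygon to ``a*x + b*y <= c``."""
    if vertices.shape[0] == 0:
        return vertices
    out: list[np.ndarray] = []
    side = vertices @ np.array([a, b]) - c
    n = vertices.shape[0]
    for i in range(n):
        j = (i + 1) % n
        vi, vj = vertices[i], vertices[j]
        if side[i] <= 0:
            out.append(vi)
        if (side[i] <= 0) != (side[j] <= 0):
            t = side[i] / (side[i] - side[j])
            out.append(vi + t * (vj - vi))
    return np.asarray(out).reshape(-1, 2)


def _clip_to_box(vertices: np.ndarray, domain: DomainRect) -> np.ndarray:
    x_min, x_max, y_min, y_max = domain.bounds
    for a, b, c in (
        (-1.0, 0.0, -x_min),
        (1.0, 0.0, x_max),
        (0.0, -1.0, -y_min),
        (0.0, 1.0, y_max),
    ):
        vertices = _clip_halfplane(vertices, a, b, c)
    return vertices


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    cross = x * np.concatenate((y[1:], y[:1])) - y * np.concatenate((x[1:], x[:1]))
    return 0.5 * abs(float(np.sum(cross)))


def voronoi_partition(points: np.ndarray, domain: DomainRect) -> VoronoiPartition:
    """Voronoi tessellation of ``points`` clipped to the domain rectangle.

    Clipping is exact: the point set is augmented with its mirror image
    across each of the four domain edges, so every original point's cell in
    the augmented diagram is bounded by the domain edges (the bisector between
    a point and its own reflection *is* the edge) and coincides inside the
    rectangle with the true clipped cell — a reflected point is never closer
    than its original to any interior location.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = points.shape[0]
    if n == 0:
        raise ValueError("need at least one point")
    if not np.all(domain.contains(points)):
        raise ValueError("out of domain: point outside the domain")
    if np.unique(points, axis=0).shape[0] != n:
        raise ValueError("duplicate point")
    x_min, x_max, y_min, y_max = domain.bounds
    if n == 1:
        box = np.array(
            [[x_min, y_min], [x_max, y_min], [x_max, y_max], [x_min, y_max]]
        )
        return VoronoiPartition(points, [box], np.array([domain.area]), domain)
    reflections = [
        np.column_stack([2 * x_min - points[:, 0], points[:, 1]]),
        np.column_stack([2 * x_max - points[:, 0], points[:, 1]]),
        np.column_stack([points[:, 0], 2 * y_min - points[:, 1]]),
        np.column_stack([points[:, 0], 2 * y_max - points[:, 1]]),
    ]
    augmented = np.vstack([points] + reflections)
    vor = Voronoi(augmented)
    cells: list[np.ndarray] = []
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # pragma: no cover - reflections bound it
            raise RuntimeError("unbounded cell despite boundary reflections")
        verts = vor.vertices[region]
        # Cells are convex; order vertices counter-clockwise around the owner.
        angles = np.arctan2(verts[:, 1] - points[i, 1], verts[:, 0] - points[i, 0])
        verts = verts[np.argsort(angles)]
        # The reflections already bound interior points' cells by the domain
        # edges; clipping is a no-op then, and handles points sitting exactly
        # on the boundary (whose own reflection coincides with them).
        verts = _clip_to_box(verts, domain)
        if verts.shape[0] < 3:  # pragma: no cover - zero-area degenerate cell
            raise RuntimeError("degenerate clipped cell")
        cells.append(verts)
        areas[i] = _polygon_area(verts)
    return VoronoiPartition(points, cells, areas, domain)


def _loo_prediction_full(
    points: np.ndarray, values: np.ndarray, domain: DomainRect, i: int
) -> np.ndarray:
    """Reference path: rebuild the surrogate without point i, evaluate at X_i."""
    mask = np.arange(points.shape[0]) != i
    try:
        reduced = SurrogateModel(points[mask], values[mask], domain)
        return evaluate(reduced, points[i : i + 1])[0]
    except ValueError:
        d2 = np.sum((points[mask] - points[i]) ** 2, axis=1)
        return values[mask][np.argmin(d2)]


def loo_errors(
    points: np.ndarray, values: np.ndarray, domain: DomainRect
) -> np.ndarray:
    """Leave-one-out errors of the linear surrogate at each support point.

    For each point i the surrogate is rebuilt from the remaining points and
    evaluated at X_i; the error is the L2 norm of the difference from the
    held-out value vector (the full model reproduces its support exactly, so
    U_0(X_i) = Y_i).  If the reduced support is degenerate (fewer than three
    points or collinear) or X_i falls outside the reduced hull, the rebuilt
    model's nearest-support fallback supplies the prediction.

    The rebuild is localized for speed: removing an interior point only
    re-triangulates its Delaunay cavity, whose new triangles use the point's
    natural neighbours, so evaluating the reduced model at X_i needs only the
    two-ring neighbourhood of i.  A hull vertex of the full support falls
    outside the reduced hull by construction, and its prediction is exactly
    the nearest remaining point's value.  Any ambiguous case falls back to a
    full rebuild, so the result is identical to the brute-force loop.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n = points.shape[0]
    if n < 4:
        raise ValueError("need at least 4 points for leave-one-out errors")
    try:
        from scipy.spatial import Delaunay

        tri = Delaunay(points)
    except QhullError as exc:
        raise ValueError("degenerate support: points are collinear") from exc
    if tri.coplanar.size:  # points qhull could not triangulate; play it safe
        return np.array(
            [
                np.linalg.norm(
                    values[i] - _loo_prediction_full(points, values, domain, i)
                )
                for i in range(n)
            ]
        )
    hull_vertices = set(int(v) for v in np.unique(tri.convex_hull))
    indptr, neighbors = tri.vertex_neighbor_vertices
    eps = np.empty(n)
    from scipy.spatial import Delaunay as _Delaunay

    for i in range(n):
        if i in hull_vertices:
            # X_i is an extreme point, hence outside the reduced hull:
            # the reduced model's fallback returns the nearest remaining value.
            mask = np.arange(n) != i
            d2 = np.sum((points[mask] - points[i]) ** 2, axis=1)
            pred = values[mask][np.argmin(d2)]
        else:
            ring1 = neighbors[indptr[i] : indptr[i + 1]]
            ring2 = np.unique(
                np.concatenate(
                    [neighbors[indptr[j] : indptr[j + 1]] for j in ring1]
                )
            )
            local = np.setdiff1d(np.union1d(ring1, ring2), [i])
            pred = None
            if local.size >= 3:
                try:
                    ltri = _Delaunay(points[local])
                    s = int(ltri.find_simplex(points[i]))
                    if s >= 0:
                        T = ltri.transform[s]
                        b = T[:2] @ (points[i] - T[2])
                        w = np.array([b[0], b[1], 1.0 - b[0] - b[1]])
                        pred = w @ values[local[ltri.simplices[s]]]
                except QhullError:
                    pred = None
            if pred is None:
                pred = _loo_prediction_full(points, values, domain, i)
        eps[i] = np.linalg.norm(values[i] - pred)
    return eps


def normalize_minmax(x: np.ndarray) -> np.ndarray:
    """Linear scaling of an array onto [0, 1]; a constant array maps to zeros.

    A constant quantity carries no ranking information, so the degenerate
    0/0 case is defined as all zeros.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty array")
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def regularized_errors(eps_loo: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """Voronoi-regularized LOO errors: sigma(eps_i) + sigma(V_i), in [0, 2].

    Both terms are min-max normalized over the current point set and weighted
    equally, so a point scores highly by having a large leave-one-out error,
    by sitting in a sparsely sampled region, or both.
    """
    eps_loo = np.asarray(eps_loo, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if eps_loo.shape != areas.shape:
        raise ValueError("eps_loo and areas must have equal length")
    return normalize_minmax(eps_loo) + normalize_minmax(areas)


def mean_weighted_loo(eps_loo: np.ndarray, areas: np.ndarray) -> float:
    """Voronoi-area-weighted mean LOO error: sum(V_i * eps_i) / sum(V_i)."""
    eps_loo = np.asarray(eps_loo, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if eps_loo.shape != areas.shape:
        raise ValueError("eps_loo and areas must have equal length")
    total = np.sum(areas)
    if total <= 0:
        raise ValueError("total Voronoi area must be positive")
    return float(np.sum(areas * eps_loo) / total)


@dataclass
class ErrorTable:
    """Per-point error diagnostics for one acquisition iteration."""

    eps_loo: np.ndarray
    areas: np.ndarray
    sigma_eps: np.ndarray
    sigma_area: np.ndarray
    eps_liv: np.ndarray

    @classmethod
    def from_errors(cls, eps_loo: np.ndarray, areas: np.ndarray) -> "ErrorTable":
        eps_loo = np.asarray(eps_loo, dtype=float)
        areas = np.asarray(areas, dtype=float)
        sigma_eps = normalize_minmax(eps_loo)
        sigma_area = normalize_minmax(areas)
        return cls(
            eps_loo=eps_loo,
            areas=areas,
            sigma_eps=sigma_eps,
            sigma_area=sigma_area,
            eps_liv=sigma_eps + sigma_area,
        )

    @property
    def mean_weighted(self) -> float:
        return mean_weighted_loo(self.eps_loo, self.areas)

    def to_dict(self) -> dict:
        return {
            "eps_loo": self.eps_loo.tolist(),
            "areas": self.areas.tolist(),
            "eps_liv": self.eps_liv.tolist(),
            "mean_weighted_loo": self.mean_weighted,
        }
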