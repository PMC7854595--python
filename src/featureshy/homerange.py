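"""Kernel-density home ranges and nearest-distance tables.

Home ranges are bivariate Gaussian KDEs of an animal's telemetry fixes,
summarised by the centroid of the fixes and the boundary contour of the
smallest region holding a chosen fraction (isopleth, default 0.95) of the
density mass.  The bandwidth matrix is the normal-reference plug-in
``H = n^(-1/3) * Sigma_hat`` (full sample covariance), with Silverman's rule
as a fallback for very small samples.

Distances from any location or contour to a feature layer are planar
Euclidean nearest distances (shapely); an empty layer yields +inf with a
warning so downstream stages can drop the class explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.geometry.base import BaseGeometry

from .landscape import FeatureLayer, LocationSet

__all__ = ["HomeRange", "kde_home_range", "nearest_distance", "build_distance_table"]

logger = logging.getLogger(__name__)

GRID_SIZE = 256  # contouring grid; box padded to 1.2x the point bounding box
MIN_POINTS = 5


@dataclass
class HomeRange:
    """KDE home range: centroid, isopleth contour polygon(s), bandwidth matrix."""

    animal_id: object
    centroid: tuple[float, float]
    contour: MultiPolygon
    bandwidth: np.ndarray  # 2x2, m^2
    isopleth: float
    year: object = None

    @property
    def area_m2(self) -> float:
        return float(self.contour.area)


def _bandwidth_matrix(pts: np.ndarray) -> np.ndarray:
    n = pts.shape[0]
    cov = np.cov(pts.T)
    if n >= 10:
        return cov * n ** (-1.0 / 3.0)  # normal-reference plug-in, d=2
    # Silverman fallback for tiny samples (diagonal, per-coordinate)
    sd = np.std(pts, axis=0, ddof=1)
    h = (sd * n ** (-1.0 / 6.0)) ** 2
    return np.diag(np.maximum(h, 1e-12))


def kde_home_range(
    points,
    isopleth: float = 0.95,
    animal_id=None,
    year=None,
    grid_size: int = GRID_SIZE,
) -> HomeRange | None:
    """Home range of one animal-year from its fixes; None if fewer than 5 points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not 0.0 < isopleth < 1.0:
        raise ValueError("isopleth must be in (0, 1)")
    n = pts.shape[0]
    if n < MIN_POINTS:
        logger.warning(
            "skipping home range for %r: only %d points (need %d)", animal_id, n, MIN_POINTS
        )
        return None

    H = _bandwidth_matrix(pts)
    sd = np.sqrt(np.diag(H))
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    half_w = max((xmax - xmin) / 2.0, 1e-9) * 1.2 + 3.0 * sd[0]
    half_h = max((ymax - ymin) / 2.0, 1e-9) * 1.2 + 3.0 * sd[1]
    gx = np.linspace(cx - half_w, cx + half_w, grid_size)
    gy = np.linspace(cy - half_h, cy + half_h, grid_size)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    grid = np.column_stack([xx.ravel(), yy.ravel()])
    dens = _kde_eval(grid, pts, H).reshape(grid_size, grid_size)

    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) * cell
    total = cum[-1]
    k = int(np.searchsorted(cum, isopleth * total))
    level = flat[min(k, flat.size - 1)]

    polygons = _contour_polygons(dens, level, gx, gy)
    contour = MultiPolygon(polygons) if polygons else MultiPolygon([])
    return HomeRange(
        animal_id=animal_id,
        centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
        contour=contour,
        bandwidth=H,
        isopleth=isopleth,
        year=year,
    )


def _kde_eval(grid: np.ndarray, pts: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Gaussian mixture density of the KDE at grid points (chunked)."""
    from scipy.linalg import solve_triangular

    L = np.linalg.cholesky(H)
    norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(H)) * pts.shape[0])
    # whiten both sets so squared distances are Mahalanobis

    g_w = solve_triangular(L, grid.T, lower=True).T
    p_w = solve_triangular(L, pts.T, lower=True).T
    out = np.empty(grid.shape[0])
    chunk = max(1, 2_000_000 // max(pts.shape[0], 1))
    for i in range(0, grid.shape[0], chunk):
        gseg = g_w[i : i + chunk]
        d2 = (
            np.sum(gseg**2, axis=1)[:, None]
            - 2.0 * gseg @ p_w.T
            + np.sum(p_w**2, axis=1)[None, :]
        )
        out[i : i + chunk] = np.exp(-0.5 * d2).sum(axis=1)
    return out * norm


def _contour_polygons(dens, level, gx, gy) -> list[Polygon]:
    from skimage import measure

    # pad with zeros so every contour closes inside the padded grid
    padded = np.pad(dens, 1, mode="constant")
    dx = gx[1] - gx[0]
    dy = gy[1] - gy[0]
    polys = []
    for ring in measure.find_contours(padded, level):
        xs = gx[0] + (ring[:, 0] - 1.0) * dx
        ys = gy[0] + (ring[:, 1] - 1.0) * dy
        if xs.size < 4:
            continue
        poly = Polygon(np.column_stack([xs, ys]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        if isinstance(poly, MultiPolygon):
            polys.extend(list(poly.geoms))
        else:
            polys.append(poly)
    # keep outer shells, subtract holes (rings nested inside another ring)
    shells = [p for p in polys if not any(q.contains(p) for q in polys if q is not p)]
    holes = [p for p in polys if p not in shells]
    out = []
    for shell in shells:
        for hole in holes:
            if shell.contains(hole):
                shell = shell.difference(hole)
        if isinstance(shell, MultiPolygon):
            out.extend(list(shell.geoms))
        elif not shell.is_empty:
            out.append(shell)
    return out


def nearest_distance(geometry, layer: FeatureLayer) -> float:
    """Nearest planar distance from a point or polygon to a feature layer.

    Polygons measure from their filled region: a feature intersecting the
    polygon gives 0.  An empty layer returns +inf with a warning.
    """
    if layer.is_empty:
        logger.warning("feature layer %r is empty; distance is +inf", layer.name)
        return float("inf")
    if isinstance(geometry, (tuple, list)) and len(geometry) == 2:
        geometry = Point(geometry)
    if not isinstance(geometry, BaseGeometry):
        raise TypeError("geometry must be a shapely geometry or an (x, y) pair")
    return float(geometry.distance(layer.union()))


def build_distance_table(
    location_sets: list[LocationSet],
    layers: list[FeatureLayer],
) -> pd.DataFrame:
    """Long-format table: one row per (location, feature class) pair.

    Columns: id, role, feature_class, distance_m.  Ordering is deterministic:
    location sets in the given order, locations by id, layers in the given
    order.
    """
    rows = []
    for loc in location_sets:
        for layer in layers:
            if layer.is_empty:
                logger.warning("feature layer %r is empty; distances are +inf", layer.name)
                d = np.full(len(loc), np.inf)
            else:
                d = layer.distances(loc.x, loc.y)
            rows.append(
                pd.DataFrame(
                    {
                        "id": loc.ids,
                        "role": loc.role,
                        "feature_class": layer.name,
                        "distance_m": d,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
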