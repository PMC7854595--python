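"""Synthetic landscapes with known avoidance ground truth.

Generates anthropogenic feature layers (points for wells/outbuildings/
residences; polylines for roads, powerlines, fences, railroads), uniform
random availability points, animal locations thinned by per-feature
suppression functions, and noisy bearing sets for the triangulation stage.
Everything is a pure function of (config, seed) so downstream stages can be
tested against ground truth without field data.

Avoidance is operationalised as suppression of an otherwise homogeneous
point process: a candidate location at nearest distance ``d`` from a feature
class is retained with weight 0/1 (hard threshold) or logistic
``1 / (1 + exp(-(d - T)/s))`` (smooth threshold with softness ``s``), and
weights multiply across feature classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, MultiLineString, MultiPoint, Point, box

__all__ = [
    "Extent",
    "FeatureSpec",
    "SuppressionFunction",
    "LandscapeConfig",
    "FeatureLayer",
    "LocationSet",
    "generate_features",
    "generate_random_points",
    "simulate_animal_locations",
    "simulate_bearings",
]

REJECTION_CAP = 10_000_000  # bounded rejection sampling, clear failure mode


@dataclass(frozen=True)
class Extent:
    """Axis-aligned study-area rectangle in projected meters."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("extent must have positive width and height")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_box(self):
        return box(self.xmin, self.ymin, self.xmax, self.ymax)

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)


@dataclass(frozen=True)
class FeatureSpec:
    """One feature class to place on the landscape.

    kind 'point' scatters ``count`` uniform points; 'line' draws ``count``
    random chords (uniform orientation and offset); 'grid' lays two
    orthogonal regular line families with ``spacing_m`` and a random phase,
    the layout of section-line fencing on surveyed plains landscapes.
    """

    name: str
    kind: str  # point | line | grid
    count: int = 0
    spacing_m: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind not in ("point", "line", "grid"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        if self.kind in ("point", "line") and self.count < 0:
            raise ValueError("count must be >= 0")
        if self.kind == "grid" and not self.spacing_m > 0:
            raise ValueError("grid features need a positive spacing_m")


@dataclass(frozen=True)
class SuppressionFunction:
    """Occupancy weight as a function of nearest distance to one feature class."""

    threshold_m: float
    softness_m: float = 25.0
    form: str = "hard"  # hard | logistic

    def __post_init__(self) -> None:
        if self.form not in ("hard", "logistic"):
            raise ValueError(f"unknown suppression form {self.form!r}")
        if not np.isfinite(self.threshold_m) or self.threshold_m < 0:
            raise ValueError("threshold must be finite and >= 0")
        if self.form == "logistic" and not self.softness_m > 0:
            raise ValueError("logistic suppression needs positive softness")

    def weight(self, distance) -> np.ndarray:
        d = np.asarray(distance, dtype=float)
        if self.form == "hard":
            return (d >= self.threshold_m).astype(float)
        return 1.0 / (1.0 + np.exp(-(d - self.threshold_m) / self.softness_m))


@dataclass(frozen=True)
class LandscapeConfig:
    """Full specification of a synthetic study area."""

    extent: Extent
    feature_specs: tuple[FeatureSpec, ...] = ()
    n_animals: int = 250
    n_random: int = 2000
    avoidance_profile: dict = field(default_factory=dict)  # name -> SuppressionFunction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 0 or self.n_random < 0:
            raise ValueError("counts must be >= 0")
        for name, sup in self.avoidance_profile.items():
            if sup.threshold_m >= self.extent.diagonal:
                raise ValueError(
                    f"threshold for {name!r} is not smaller than the extent diagonal"
                )


@dataclass
class FeatureLayer:
    """Named collection of point or polyline geometries for one feature class."""

    name: str
    kind: str  # point | line
    geometries: list

    def __post_init__(self) -> None:
        self._union = None

    @property
    def is_empty(self) -> bool:
        return len(self.geometries) == 0

    def union(self):
        if self._union is None and not self.is_empty:
            if self.kind == "point":
                self._union = MultiPoint(self.geometries)
            else:
                self._union = MultiLineString(
                    [g for geom in self.geometries for g in _as_lines(geom)]
                )
        return self._union

    def distances(self, x, y) -> np.ndarray:
        """Nearest distance from each (x, y) to the layer; +inf if empty."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if self.is_empty:
            return np.full(x.shape, np.inf)
        pts = shapely.points(x, y)
        return shapely.distance(pts, self.union())


def _as_lines(geom):
    if isinstance(geom, MultiLineString):
        return list(geom.geoms)
    return [geom]


@dataclass
class LocationSet:
    """Labeled planar points: animal locations, random points, leks or nests."""

    x: np.ndarray
    y: np.ndarray
    role: str
    ids: np.ndarray = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")
        if self.ids is None:
            self.ids = np.arange(self.x.size)

    def __len__(self) -> int:
        return self.x.size

    def points(self):
        return [Point(px, py) for px, py in zip(self.x, self.y)]


def generate_features(config: LandscapeConfig) -> list[FeatureLayer]:
    """Place every configured feature class; deterministic given config.seed."""
    if config.extent.area <= 0:
        raise ValueError("zero-area extent")
    rng = np.random.default_rng(config.seed)
    ext = config.extent
    layers = []
    for spec in config.feature_specs:
        if spec.kind == "point":
            xs = rng.uniform(ext.xmin, ext.xmax, spec.count)
            ys = rng.uniform(ext.ymin, ext.ymax, spec.count)
            geoms = [Point(px, py) for px, py in zip(xs, ys)]
            layers.append(FeatureLayer(spec.name, "point", geoms))
        elif spec.kind == "line":
            geoms = [_random_chord(ext, rng) for _ in range(spec.count)]
            geoms = [g for g in geoms if g is not None]
            layers.append(FeatureLayer(spec.name, "line", geoms))
        else:  # grid
            geoms = _grid_lines(ext, spec.spacing_m, rng)
            layers.append(FeatureLayer(spec.name, "line", geoms))
    return layers


def _random_chord(ext: Extent, rng) -> LineString | None:
    """Chord with uniform orientation through a uniform interior point, clipped."""
    px = rng.uniform(ext.xmin, ext.xmax)
    py = rng.uniform(ext.ymin, ext.ymax)
    ang = rng.uniform(0.0, np.pi)
    r = 2.0 * ext.diagonal
    dx, dy = r * np.cos(ang), r * np.sin(ang)
    long_line = LineString([(px - dx, py - dy), (px + dx, py + dy)])
    clipped = long_line.intersection(ext.as_box())
    if clipped.is_empty:
        return None
    if isinstance(clipped, MultiLineString):
        clipped = max(clipped.geoms, key=lambda g: g.length)
    return clipped


def _grid_lines(ext: Extent, spacing: float, rng) -> list[LineString]:
    # the grid continues beyond the study window (the window samples a larger
    # surveyed landscape), so lines within one spacing of the extent are kept
    phase_x = rng.uniform(0.0, spacing)
    phase_y = rng.uniform(0.0, spacing)
    pad = spacing
    lines = []
    x = ext.xmin + phase_x - spacing
    while x <= ext.xmax + pad:
        if ext.xmin - pad <= x:
            lines.append(LineString([(x, ext.ymin - pad), (x, ext.ymax + pad)]))
        x += spacing
    y = ext.ymin + phase_y - spacing
    while y <= ext.ymax + pad:
        if ext.ymin - pad <= y:
            lines.append(LineString([(ext.xmin - pad, y), (ext.xmax + pad, y)]))
        y += spacing
    return lines


def generate_random_points(extent: Extent, n: int, seed=None) -> LocationSet:
    """n i.i.d. uniform points over the extent (the availability sample)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return LocationSet(
        x=rng.uniform(extent.xmin, extent.xmax, n),
        y=rng.uniform(extent.ymin, extent.ymax, n),
        role="random",
    )


def simulate_animal_locations(
    layers: list[FeatureLayer],
    profile: dict,
    n: int,
    extent: Extent,
    seed=None,
    role: str = "homerange_centroid",
    batch: int = 8192,
) -> LocationSet:
    """Rejection-sample n locations with acceptance weight from the profile.

    The acceptance weight of a candidate is the product over feature classes
    of the suppression weight at its nearest distance to that class; with an
    empty profile this reduces to uniform sampling.
    """
    by_name = {layer.name: layer for layer in layers}
    for name in profile:
        if name not in by_name:
            raise ValueError(f"avoidance profile names unknown feature class {name!r}")
    rng = np.random.default_rng(seed)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    got = 0
    attempts = 0
    while got < n:
        if attempts >= REJECTION_CAP:
            raise RuntimeError(
                f"rejection sampling exceeded {REJECTION_CAP} attempts "
                f"({got}/{n} accepted); thresholds may cover the extent"
            )
        m = min(batch, REJECTION_CAP - attempts)
        cx = rng.uniform(extent.xmin, extent.xmax, m)
        cy = rng.uniform(extent.ymin, extent.ymax, m)
        w = np.ones(m)
        for name, sup in profile.items():
            d = by_name[name].distances(cx, cy)
            w *= sup.weight(d)
        keep = rng.random(m) < w
        xs.append(cx[keep])
        ys.append(cy[keep])
        got += int(keep.sum())
        attempts += m
    x = np.concatenate(xs)[:n]
    y = np.concatenate(ys)[:n]
    return LocationSet(x=x, y=y, role=role)


def simulate_bearings(
    true_point,
    stations,
    noise_sd_deg: float = 0.0,
    outlier_rate: float = 0.0,
    seed=None,
):
    """Azimuths from each station toward true_point with angular noise.

    Noise is wrapped normal in degrees; with probability ``outlier_rate`` a
    bearing is replaced by a uniform azimuth.  Returns a list of
    BearingObservation for the triangulation stage.
    """
    from .triangulation import BearingObservation

    stations = np.asarray(stations, dtype=float)
    if stations.ndim != 2 or stations.shape[0] < 1:
        raise ValueError("need at least one station as an (n, 2) array")
    tx, ty = float(true_point[0]), float(true_point[1])
    rng = np.random.default_rng(seed)
    out = []
    for sx, sy in stations:
        az = math.degrees(math.atan2(tx - sx, ty - sy))  # clockwise from north
        if rng.random() < outlier_rate:
            az = rng.uniform(0.0, 360.0)
        else:
            az += rng.normal(0.0, noise_sd_deg) if noise_sd_deg > 0 else 0.0
        out.append(BearingObservation(station=(sx, sy), azimuth_deg=az % 360.0))
    return out
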