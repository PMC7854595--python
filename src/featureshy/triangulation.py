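"""Planar location estimation from radio-telemetry bearings.

Implements the iteratively reweighted maximum-likelihood bearing-intersection
estimator of Lenth (1981).  For von Mises angular errors the score equations
reduce, after linearisation, to weighted least squares on the signed
perpendicular distances from the candidate point to each bearing line, with
weights 1/d_i^2 (d_i = distance from station i to the current estimate), so
the fixed point minimises the squared angular residual objective.

When the plain iteration fails to converge, robust M-estimator variants
(Andrews sine, Huber) reweight standardised angular residuals; they use a
damped (step-halving) update since they are invoked exactly on the sets the
plain iteration could not handle.  Azimuths are degrees clockwise from north
(surveying convention); internal math is in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BearingObservation",
    "TelemetryFix",
    "angular_objective",
    "lenth_mle",
    "robust_estimate",
    "triangulate",
]

HUBER_K = 1.345  # classical 95%-efficiency constant on standardised residuals
ANDREWS_C = 1.5  # sine-wave cutoff at |t| = 1.5*pi


@dataclass(frozen=True)
class BearingObservation:
    """One azimuth reading: station position (m) and bearing clockwise from north."""

    station: tuple[float, float]
    azimuth_deg: float

    def __post_init__(self) -> None:
        sx, sy = self.station
        if not (np.isfinite(sx) and np.isfinite(sy) and np.isfinite(self.azimuth_deg)):
            raise ValueError("station coordinates and azimuth must be finite")
        object.__setattr__(self, "azimuth_deg", float(self.azimuth_deg) % 360.0)


@dataclass(frozen=True)
class TelemetryFix:
    """Triangulated location with provenance of the estimator that produced it."""

    location: tuple[float, float]
    estimator_used: str  # mle | andrews | huber
    converged: bool
    n_bearings: int


def _unpack(bearings):
    if len(bearings) < 2:
        raise ValueError("need at least 2 bearings to triangulate")
    sx = np.array([b.station[0] for b in bearings])
    sy = np.array([b.station[1] for b in bearings])
    if np.allclose(sx, sx[0]) and np.allclose(sy, sy[0]):
        raise ValueError("all stations identical; bearings cannot intersect")
    az = np.radians([b.azimuth_deg for b in bearings])
    return sx, sy, np.sin(az), np.cos(az)


def angular_objective(point, bearings) -> float:
    """Sum of squared angular residuals (radians) at a candidate point.

    The residual for bearing i is the wrapped difference between the observed
    azimuth and the azimuth from station i to the candidate point.  This is
    the objective the MLE minimises (up to linearisation) and the one the
    grid-search oracle in the tests scans.
    """
    x, y = point
    sx = np.array([b.station[0] for b in bearings])
    sy = np.array([b.station[1] for b in bearings])
    az = np.radians([b.azimuth_deg for b in bearings])
    implied = np.arctan2(x - sx, y - sy)
    delta = np.angle(np.exp(1j * (az - implied)))
    return float(np.sum(delta**2))


def _solve_weighted(sx, sy, s, c, w):
    """Weighted LS solution for the intersection of bearing lines.

    Line i passes through (sx_i, sy_i) with direction (s_i, c_i); its signed
    perpendicular residual at (x, y) is c_i (x - sx_i) - s_i (y - sy_i).
    """
    a11 = np.sum(w * c * c)
    a12 = -np.sum(w * c * s)
    a22 = np.sum(w * s * s)
    r0 = c * sx - s * sy
    b1 = np.sum(w * c * r0)
    b2 = -np.sum(w * s * r0)
    det = a11 * a22 - a12 * a12
    if not np.isfinite(det) or abs(det) < 1e-12 * max(a11 * a22, 1e-30):
        return None
    x = (a22 * b1 - a12 * b2) / det
    y = (a11 * b2 - a12 * b1) / det
    return x, y


def _angular_residuals(x, y, sx, sy, s, c):
    implied = np.arctan2(x - sx, y - sy)
    observed = np.arctan2(s, c)
    return np.angle(np.exp(1j * (observed - implied)))


def _irls(
    bearings,
    psi_weight=None,
    max_iter: int = 100,
    tol: float = 1e-8,
    damped: bool = False,
):
    sx, sy, s, c = _unpack(bearings)
    span = max(np.ptp(sx) + np.ptp(sy), 1.0)
    sol = _solve_weighted(sx, sy, s, c, np.ones_like(sx))
    if sol is None:
        return None, False
    x, y = sol
    converged = False
    obj_prev = angular_objective((x, y), bearings) if damped else None
    for _ in range(max_iter):
        d = np.hypot(x - sx, y - sy)
        d = np.maximum(d, 1e-6)
        w = 1.0 / d**2
        if psi_weight is not None:
            delta = _angular_residuals(x, y, sx, sy, s, c)
            w = w * psi_weight(delta)
            if np.all(w <= 0):
                return (x, y), False
        sol = _solve_weighted(sx, sy, s, c, w)
        if sol is None:
            return (x, y), False
        nx, ny = sol
        if damped:
            # step-halving: retreat toward the previous iterate if the
            # angular objective worsened (stabilises difficult sets)
            for _ in range(20):
                obj_new = angular_objective((nx, ny), bearings)
                if obj_new <= obj_prev + 1e-15:
                    break
                nx, ny = 0.5 * (nx + x), 0.5 * (ny + y)
            obj_prev = angular_objective((nx, ny), bearings)
        step = math.hypot(nx - x, ny - y)
        x, y = nx, ny
        if not np.isfinite(x) or not np.isfinite(y) or math.hypot(x, y) > 1e3 * span + 1e9:
            return (x, y), False  # divergence toward an intersection at infinity
        if step < tol * (1.0 + math.hypot(x, y)):
            converged = True
            break
    return (x, y), converged


def lenth_mle(bearings, max_iter: int = 100, tol: float = 1e-8) -> TelemetryFix:
    """Lenth's iteratively reweighted ML bearing-intersection estimate."""
    loc, ok = _irls(bearings, psi_weight=None, max_iter=max_iter, tol=tol, damped=False)
    if loc is None:
        return TelemetryFix((float("nan"), float("nan")), "mle", False, len(bearings))
    return TelemetryFix((float(loc[0]), float(loc[1])), "mle", bool(ok), len(bearings))


def _huber_weight(delta):
    scale = np.median(np.abs(delta))
    scale = max(scale, 1e-8)
    t = np.abs(delta) / scale
    return np.minimum(1.0, HUBER_K / np.maximum(t, 1e-12))


def _andrews_weight(delta):
    scale = np.median(np.abs(delta))
    scale = max(scale, 1e-8)
    t = delta / scale
    w = np.zeros_like(t)
    inside = np.abs(t) <= ANDREWS_C * np.pi
    tt = t[inside] / ANDREWS_C
    with np.errstate(invalid="ignore", divide="ignore"):
        w_in = np.where(np.abs(tt) < 1e-12, 1.0, np.sin(tt) / tt)
    w[inside] = w_in
    return np.maximum(w, 0.0)


def robust_estimate(bearings, method: str = "andrews", max_iter: int = 100, tol: float = 1e-8) -> TelemetryFix:
    """M-estimator variant of the bearing intersection (Andrews sine or Huber)."""
    if method == "andrews":
        psi = _andrews_weight
    elif method == "huber":
        psi = _huber_weight
    else:
        raise ValueError(f"unknown robust method {method!r}")
    loc, ok = _irls(bearings, psi_weight=psi, max_iter=max_iter, tol=tol, damped=True)
    if loc is None:
        return TelemetryFix((float("nan"), float("nan")), method, False, len(bearings))
    return TelemetryFix((float(loc[0]), float(loc[1])), method, bool(ok), len(bearings))


def triangulate(bearings, max_iter: int = 100, tol: float = 1e-8) -> TelemetryFix:
    """MLE first; on non-convergence fall back to Andrews, then Huber."""
    fix = lenth_mle(bearings, max_iter=max_iter, tol=tol)
    if fix.converged:
        return fix
    for method in ("andrews", "huber"):
        fix = robust_estimate(bearings, method=method, max_iter=max_iter, tol=tol)
        if fix.converged:
            return fix
    return fix  # converged=False only if every estimator failed
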