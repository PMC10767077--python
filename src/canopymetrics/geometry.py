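"""Geometric primitives: circle fitting, slicing, hulls, cylinder distance.

These are the building blocks of the measurement pipeline: DBH and tree
location come from least-squares circle fits to horizontal trunk slices,
crown projection area from a 2D convex hull, and QSM fit quality from
point-to-cylinder distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateInputError
from .pointcloud_io import PointCloud

__all__ = [
    "CircleFit",
    "Cylinder",
    "fit_circle",
    "horizontal_slice",
    "convex_hull_area",
    "point_to_cylinder_distance",
]


@dataclass(frozen=True)
class CircleFit:
    """Result of a geometric least-squares circle fit.

    ``rms_residual`` is the root mean square of the signed radial residuals
    ``||p - c|| - r``.
    """

    center_x: float
    center_y: float
    radius: float
    rms_residual: float
    n_points: int


@dataclass(frozen=True)
class Cylinder:
    """A finite closed cylinder: start point, unit axis, length, radius."""

    start: np.ndarray
    axis: np.ndarray
    length: float
    radius: float

    def __post_init__(self):
        start = np.asarray(self.start, dtype=np.float64).reshape(3)
        axis = np.asarray(self.axis, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(axis)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"axis must be a unit vector, |axis| = {norm}")
        if not self.length > 0:
            raise ValueError("length must be positive")
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "axis", axis / norm)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.length * self.axis

    @property
    def volume(self) -> float:
        """Volume in cubic meters."""
        return float(np.pi * self.radius**2 * self.length)


def _as_2d(points) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise DegenerateInputError(
            f"expected an (n, 2) point array, got shape {pts.shape}"
        )
    return pts[:, :2]


def _check_not_collinear(pts: np.ndarray) -> None:
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] <= 1e-9 * max(1.0, svals[0]):
        raise DegenerateInputError("points are collinear within tolerance")


def fit_circle(points) -> CircleFit:
    """Fit the circle minimizing the sum of squared radial residuals.

    Algebraic (Kasa) linear least squares provides the start point; a
    geometric Gauss-Newton refinement (scipy ``least_squares``) then
    minimizes ``sum((||p - c|| - r)^2)`` over center and radius. Exact on
    noise-free circles.

    Raises
    ------
    DegenerateInputError
        For fewer than 3 points or collinear points.
    """
    pts = _as_2d(points)
    n = pts.shape[0]
    if n < 3:
        raise DegenerateInputError(f"circle fit needs >= 3 points, got {n}")
    _check_not_collinear(pts)

    x, y = pts[:, 0], pts[:, 1]
    # Kasa: ||p||^2 = 2 cx x + 2 cy y + (r^2 - cx^2 - cy^2)
    a_mat = np.column_stack([2 * x, 2 * y, np.ones(n)])
    rhs = x * x + y * y
    (cx, cy, c), *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        raise DegenerateInputError("algebraic circle fit collapsed")
    r0 = float(np.sqrt(r2))

    def residuals(params):
        px, py, pr = params
        return np.hypot(x - px, y - py) - pr

    sol = least_squares(
        residuals, x0=[cx, cy, r0], method="lm", xtol=1e-15, ftol=1e-15
    )
    cx, cy, r = sol.x
    if r <= 0:
        raise DegenerateInputError("circle fit produced non-positive radius")
    res = residuals(sol.x)
    return CircleFit(
        center_x=float(cx),
        center_y=float(cy),
        radius=float(r),
        rms_residual=float(np.sqrt(np.mean(res**2))),
        n_points=n,
    )


def horizontal_slice(cloud: PointCloud, z_lo: float, z_hi: float) -> PointCloud:
    """Points with ``z_lo <= z < z_hi`` (half-open), order preserved."""
    if not z_lo < z_hi:
        raise ValueError(f"need z_lo < z_hi, got [{z_lo}, {z_hi})")
    mask = (cloud.z >= z_lo) & (cloud.z < z_hi)
    return cloud.take(mask)


def convex_hull_area(points) -> float:
    """Area of the 2D convex hull (shoelace over hull vertices, via qhull).

    Duplicate and interior points do not change the result. Raises
    :class:`DegenerateInputError` for fewer than 3 distinct non-collinear
    points.
    """
    pts = _as_2d(points)
    if pts.shape[0] < 3:
        raise DegenerateInputError(
            f"convex hull needs >= 3 points, got {pts.shape[0]}"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateInputError(
            f"degenerate hull input (collinear points?): {exc}"
        ) from None
    # For a 2D hull, qhull's "volume" is the enclosed area.
    return float(hull.volume)


def point_to_cylinder_distance(points, cylinder: Cylinder):
    """Euclidean distance from point(s) to a finite solid cylinder.

    The cylinder is treated as a solid: points on or inside the closed
    envelope return 0. For a point whose axial projection lies within
    ``[0, length]`` the distance is ``max(0, radial - radius)``; beyond the
    caps it is the distance to the nearest cap disk (face or rim).

    Accepts a single (3,) point or an (n, 3) array; returns a float or an
    (n,) array accordingly.
    """
    pts = np.asarray(points, dtype=np.float64)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)

    rel = pts - cylinder.start
    t = rel @ cylinder.axis
    radial_vec = rel - np.outer(t, cylinder.axis)
    radial = np.linalg.norm(radial_vec, axis=1)

    dr = radial - cylinder.radius
    dz = np.maximum(np.maximum(-t, t - cylinder.length), 0.0)
    lateral = np.maximum(dr, 0.0)
    dist = np.where(
        dz == 0.0, lateral, np.where(dr <= 0.0, dz, np.hypot(dz, dr))
    )
    return float(dist[0]) if single else dist
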