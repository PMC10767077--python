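"""The whole-tree structure measurement pipeline.

From one cleaned single-tree point cloud this module derives:

* tree location - center of a circle fitted to the lowest 30 cm slice,
* DBH - twice the radius of a circle fitted to the 1.27-1.33 m slice above
  the tree base,
* tree height - vertical extent (max z - min z),
* crown start height - first 10 cm slice, scanning upward from the DBH
  slice, whose fitted radius jumps by >= 20% over the previous fit,
* crown radii in 72 azimuths (5 degree steps) - the farthest horizontal
  point distance inside a 10 cm vertical slab per direction, optionally
  repeated in 2 m height bands up to 30 m,
* maximum crown diameter - largest sum of opposite-direction radii,
* crown projection area - 2D convex hull of the crown's XY projection.

``measure_tree`` composes these stages after k-NN outlier removal and
reports failed stages as missing values with a machine-readable failure
log; it never fabricates a metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults as dflt
from .errors import DegenerateInputError, MeasurementError
from .geometry import CircleFit, convex_hull_area, fit_circle, horizontal_slice
from .pointcloud_io import AffineTransform, PointCloud
from .preprocess import remove_outliers

__all__ = [
    "TreeMetrics",
    "estimate_location",
    "estimate_dbh",
    "estimate_crown_start",
    "estimate_tree_height",
    "crown_radii_72",
    "crown_radii_by_height",
    "max_crown_diameter",
    "crown_projection_area",
    "measure_tree",
    "direction_angles",
    "metrics_columns",
    "metrics_to_frame",
    "write_metrics_csv",
]


def direction_angles(n_directions: int = dflt.N_DIRECTIONS) -> np.ndarray:
    """Azimuths in degrees, counterclockwise from +x: 0, 5, ..., 355."""
    return np.arange(n_directions) * (360.0 / n_directions)


@dataclass
class TreeMetrics:
    """One tree's structural record (the main dataset row).

    Scalar metrics that could not be estimated are ``None`` and explained in
    ``failures``; empty crown directions are genuine zeros.
    """

    date: str = ""
    project_id: str = ""
    tree_id: str = ""
    botanical_name: str | None = None
    location: np.ndarray | None = None
    location_global: np.ndarray | None = None
    dbh: float | None = None
    tree_height: float | None = None
    crown_start_height: float | None = None
    crown_diameter_max: float | None = None
    crown_projection_area: float | None = None
    total_volume_l: float | None = None
    crown_radii: np.ndarray | None = None
    crown_radii_by_height: np.ndarray | None = None
    crown_fallback_whole_cloud: bool = False
    failures: dict = field(default_factory=dict)


def estimate_location(
    cloud: PointCloud,
    slice_height: float = dflt.LOCATION_SLICE_HEIGHT,
    min_points: int = dflt.MIN_CIRCLE_POINTS,
) -> tuple[np.ndarray, CircleFit]:
    """Tree location: (x, y) from a circle fitted to the lowest slice of the
    cloud, z at the tree base (minimum z)."""
    if len(cloud) == 0:
        raise MeasurementError("location", "empty cloud")
    base_z = float(cloud.z.min())
    sl = horizontal_slice(cloud, base_z, base_z + slice_height)
    if len(sl) < min_points:
        raise MeasurementError(
            "location",
            f"slice [{base_z:.3f}, {base_z + slice_height:.3f}) has "
            f"{len(sl)} points (< {min_points})",
        )
    try:
        fit = fit_circle(sl.xyz[:, :2])
    except DegenerateInputError as exc:
        raise MeasurementError("location", str(exc)) from None
    return np.array([fit.center_x, fit.center_y, base_z]), fit


def estimate_dbh(
    cloud: PointCloud,
    base_z: float,
    slice_lo: float = dflt.DBH_SLICE_LO,
    slice_hi: float = dflt.DBH_SLICE_HI,
    min_points: int = dflt.MIN_CIRCLE_POINTS,
) -> tuple[float, CircleFit]:
    """DBH: twice the radius of the circle fitted to the breast-height slice
    ``[base_z + slice_lo, base_z + slice_hi)``."""
    sl = horizontal_slice(cloud, base_z + slice_lo, base_z + slice_hi)
    if len(sl) < min_points:
        raise MeasurementError(
            "dbh",
            f"slice [{base_z + slice_lo:.3f}, {base_z + slice_hi:.3f}) has "
            f"{len(sl)} points (< {min_points})",
        )
    try:
        fit = fit_circle(sl.xyz[:, :2])
    except DegenerateInputError as exc:
        raise MeasurementError("dbh", str(exc)) from None
    return 2.0 * fit.radius, fit


def estimate_crown_start(
    cloud: PointCloud,
    base_z: float,
    initial_radius: float,
    tree_height: float,
    jump: float = dflt.CROWN_JUMP,
    slice_height: float = dflt.SLICE_HEIGHT,
    scan_cap: float = dflt.CROWN_SCAN_CAP,
    min_points: int = dflt.MIN_CIRCLE_POINTS,
    scan_start: float = dflt.DBH_SLICE_HI,
) -> float | None:
    """Crown start height above the tree base, or ``None`` if not found.

    Contiguous ``slice_height`` slices are scanned upward from the top of
    the DBH slice. Each slice with at least ``min_points`` non-degenerate
    points gets a circle fit; the first whose radius is >= ``jump`` times
    the previous successful fit marks the crown base and the height of the
    slice bottom above the base is returned. Slices with too few points are
    skipped without updating the reference radius, which starts at the
    DBH-slice radius. The scan stops at ``scan_cap`` of the tree height.
    """
    prev_radius = initial_radius
    z = base_z + scan_start
    z_cap = base_z + scan_cap * tree_height
    while z < z_cap:
        sl = horizontal_slice(cloud, z, z + slice_height)
        if len(sl) >= min_points:
            try:
                fit = fit_circle(sl.xyz[:, :2])
            except DegenerateInputError:
                fit = None
            if fit is not None:
                if fit.radius >= jump * prev_radius:
                    return z - base_z
                prev_radius = fit.radius
        z += slice_height
    return None


def estimate_tree_height(cloud: PointCloud) -> float:
    """Vertical extent of the cloud: max z minus min z."""
    if len(cloud) < 2:
        raise MeasurementError(
            "tree_height", f"needs >= 2 points, got {len(cloud)}"
        )
    return float(cloud.z.max() - cloud.z.min())


def _slab_radii(
    xy: np.ndarray,
    center: np.ndarray,
    n_directions: int,
    slab_width: float,
) -> np.ndarray:
    """Max horizontal distance from ``center`` per azimuth, within a vertical
    slab of total width ``slab_width`` on the positive side of each
    direction. Empty directions give 0."""
    radii = np.zeros(n_directions)
    if xy.shape[0] == 0:
        return radii
    rel = xy - center[:2]
    dist = np.linalg.norm(rel, axis=1)
    half = slab_width / 2.0
    angles = np.deg2rad(direction_angles(n_directions))
    for i, theta in enumerate(angles):
        u = np.array([np.cos(theta), np.sin(theta)])
        along = rel @ u
        across = rel[:, 0] * (-u[1]) + rel[:, 1] * u[0]
        mask = (np.abs(across) <= half) & (along > 0)
        if mask.any():
            radii[i] = dist[mask].max()
    return radii


def crown_radii_72(
    cloud: PointCloud,
    location: np.ndarray,
    crown_start: float | None,
    base_z: float | None = None,
    n_directions: int = dflt.N_DIRECTIONS,
    slab_width: float = dflt.SLAB_WIDTH,
) -> np.ndarray:
    """Crown radius per azimuth (0, 5, ..., 355 degrees ccw from +x).

    Uses points at or above ``base_z + crown_start``; when ``crown_start``
    is ``None`` the whole cloud is used (crownless fallback). Per direction,
    the radius is the largest horizontal distance from ``location`` to a
    point inside the 10 cm vertical slab through the location, restricted to
    the positive half of that direction; directions without points give 0.
    """
    if base_z is None:
        base_z = float(location[2])
    if crown_start is None:
        crown = cloud
    else:
        crown = cloud.take(cloud.z >= base_z + crown_start)
    return _slab_radii(
        crown.xyz[:, :2], np.asarray(location, dtype=float), n_directions,
        slab_width,
    )


def crown_radii_by_height(
    cloud: PointCloud,
    location: np.ndarray,
    base_z: float | None = None,
    band_height: float = dflt.BAND_HEIGHT,
    max_height: float = dflt.MAX_BAND_HEIGHT,
    n_directions: int = dflt.N_DIRECTIONS,
    slab_width: float = dflt.SLAB_WIDTH,
) -> np.ndarray:
    """Directional radii per height band: rows are the bands [0,2), [2,4),
    ..., [28,30) meters above the tree base, columns the 72 azimuths.

    All cloud points are used (bands below the crown measure the trunk);
    empty bands are all zeros.
    """
    if base_z is None:
        base_z = float(location[2])
    n_bands = int(round(max_height / band_height))
    out = np.zeros((n_bands, n_directions))
    center = np.asarray(location, dtype=float)
    for k in range(n_bands):
        lo = base_z + k * band_height
        band = horizontal_slice(cloud, lo, lo + band_height)
        out[k] = _slab_radii(
            band.xyz[:, :2], center, n_directions, slab_width
        )
    return out


def max_crown_diameter(radii: np.ndarray) -> float:
    """Largest sum of opposite-direction radii: max_i r[i] + r[i + 180deg]."""
    radii = np.asarray(radii, dtype=float)
    n = radii.shape[0]
    if n % 2 != 0:
        raise ValueError("need an even number of directions")
    opposite = np.roll(radii, -n // 2)
    return float((radii + opposite).max())


def crown_projection_area(
    cloud: PointCloud,
    crown_start: float | None,
    base_z: float,
) -> float:
    """Area of the 2D convex hull of the crown's XY projection."""
    if crown_start is None:
        crown = cloud
    else:
        crown = cloud.take(cloud.z >= base_z + crown_start)
    if len(crown) < 3:
        raise MeasurementError(
            "crown_projection_area",
            f"needs >= 3 crown points, got {len(crown)}",
        )
    try:
        return convex_hull_area(crown.xyz[:, :2])
    except DegenerateInputError as exc:
        raise MeasurementError("crown_projection_area", str(exc)) from None


def measure_tree(
    cloud: PointCloud,
    *,
    date: str = "",
    project_id: str = "",
    tree_id: str = "",
    botanical_name: str | None = None,
    transform: AffineTransform | None = None,
    cylinders=None,
    k: int = dflt.K_NEIGHBORS,
    outlier_threshold: float = dflt.OUTLIER_THRESHOLD,
    crown_jump: float = dflt.CROWN_JUMP,
    slice_height: float = dflt.SLICE_HEIGHT,
    slab_width: float = dflt.SLAB_WIDTH,
    min_circle_points: int = dflt.MIN_CIRCLE_POINTS,
) -> TreeMetrics:
    """Run the full measurement pipeline on one raw single-tree cloud.

    Stages: outlier removal, location, DBH, crown start, tree height, crown
    radii (72 azimuths), max crown diameter, crown projection area, and
    height-banded radii. Stage failures are recorded in ``failures`` and the
    affected metrics left ``None``. ``location_global`` is populated when a
    project-to-global ``transform`` is given; ``total_volume_l`` when a QSM
    cylinder table is given.

    Raises ``MeasurementError`` only for an empty input cloud.
    """
    if len(cloud) == 0:
        raise MeasurementError("input", "empty point cloud")

    metrics = TreeMetrics(
        date=date,
        project_id=project_id,
        tree_id=tree_id,
        botanical_name=botanical_name,
    )

    report = remove_outliers(cloud, k=k, threshold=outlier_threshold)
    clean = report.kept
    if len(clean) == 0:
        metrics.failures["outliers"] = "all points removed as outliers"
        return metrics
    base_z = float(clean.z.min())

    dbh_fit = None
    try:
        metrics.location, _ = estimate_location(
            clean, min_points=min_circle_points
        )
        if transform is not None:
            metrics.location_global = transform.apply(metrics.location)
    except MeasurementError as exc:
        metrics.failures["location"] = str(exc)

    try:
        metrics.dbh, dbh_fit = estimate_dbh(
            clean, base_z, min_points=min_circle_points
        )
    except MeasurementError as exc:
        metrics.failures["dbh"] = str(exc)

    try:
        metrics.tree_height = estimate_tree_height(clean)
    except MeasurementError as exc:
        metrics.failures["tree_height"] = str(exc)

    if dbh_fit is not None and metrics.tree_height is not None:
        crown_start = estimate_crown_start(
            clean,
            base_z,
            dbh_fit.radius,
            metrics.tree_height,
            jump=crown_jump,
            slice_height=slice_height,
            min_points=min_circle_points,
        )
        if crown_start is None:
            metrics.failures["crown_start"] = (
                "no slice with a >= "
                f"{100 * (crown_jump - 1):.0f}% radius jump below "
                f"{100 * dflt.CROWN_SCAN_CAP:.0f}% of tree height"
            )
        metrics.crown_start_height = crown_start
    else:
        metrics.failures.setdefault(
            "crown_start", "requires a DBH fit and a tree height"
        )

    if metrics.crown_start_height is None:
        metrics.crown_fallback_whole_cloud = True

    if metrics.location is not None:
        metrics.crown_radii = crown_radii_72(
            clean,
            metrics.location,
            metrics.crown_start_height,
            base_z=base_z,
            slab_width=slab_width,
        )
        metrics.crown_diameter_max = max_crown_diameter(metrics.crown_radii)
        try:
            metrics.crown_projection_area = crown_projection_area(
                clean, metrics.crown_start_height, base_z
            )
        except MeasurementError as exc:
            metrics.failures["crown_projection_area"] = str(exc)
        metrics.crown_radii_by_height = crown_radii_by_height(
            clean, metrics.location, base_z=base_z, slab_width=slab_width
        )
    else:
        metrics.failures.setdefault(
            "crown_radii", "requires the tree location"
        )

    if cylinders is not None:
        from .qsm_graph import total_volume

        metrics.total_volume_l = total_volume(cylinders)

    return metrics


# ---------------------------------------------------------------------------
# tabular output


def _deg_token(deg: int) -> str:
    """355 -> '3_55', 5 -> '0_05' (hundreds digit, then two digits)."""
    return f"{deg // 100}_{deg % 100:02d}"


def metrics_columns(
    n_directions: int = dflt.N_DIRECTIONS,
    band_height: float = dflt.BAND_HEIGHT,
    max_height: float = dflt.MAX_BAND_HEIGHT,
) -> list[str]:
    """Column names of the tree-structure table, in canonical order."""
    cols = [
        "date",
        "projectID",
        "treeID",
        "botanical.name",
        "location.x",
        "location.y",
        "location.z",
        "location.lat",
        "location.long",
        "location.alt",
        "DBH(m)",
        "treeHeight(m)",
        "crownStartHeight(m)",
        "crownDiameterMax(m)",
        "crownProjectionArea(m2)",
        "totalVolume(L)",
    ]
    degs = [int(d) for d in direction_angles(n_directions)]
    cols += [f"crown{_deg_token(d)}d_m_" for d in degs]
    n_bands = int(round(max_height / band_height))
    for k in range(n_bands):
        lo = int(k * band_height)
        cols += [f"cr_{lo:02d}m{_deg_token(d)}d_m_" for d in degs]
    return cols


def metrics_to_frame(metrics_list) -> pd.DataFrame:
    """Assemble TreeMetrics records into the canonical one-row-per-tree table."""
    if isinstance(metrics_list, TreeMetrics):
        metrics_list = [metrics_list]
    cols = metrics_columns()
    rows = []
    for m in metrics_list:
        loc = m.location if m.location is not None else [np.nan] * 3
        glob = (
            m.location_global
            if m.location_global is not None
            else [np.nan] * 3
        )
        row = {
            "date": m.date,
            "projectID": m.project_id,
            "treeID": m.tree_id,
            "botanical.name": m.botanical_name,
            "location.x": loc[0],
            "location.y": loc[1],
            "location.z": loc[2],
            "location.lat": glob[0],
            "location.long": glob[1],
            "location.alt": glob[2],
            "DBH(m)": m.dbh,
            "treeHeight(m)": m.tree_height,
            "crownStartHeight(m)": m.crown_start_height,
            "crownDiameterMax(m)": m.crown_diameter_max,
            "crownProjectionArea(m2)": m.crown_projection_area,
            "totalVolume(L)": m.total_volume_l,
        }
        degs = [int(d) for d in direction_angles()]
        radii = (
            m.crown_radii
            if m.crown_radii is not None
            else np.full(len(degs), np.nan)
        )
        for d, r in zip(degs, radii):
            row[f"crown{_deg_token(d)}d_m_"] = r
        n_bands = int(round(dflt.MAX_BAND_HEIGHT / dflt.BAND_HEIGHT))
        banded = (
            m.crown_radii_by_height
            if m.crown_radii_by_height is not None
            else np.full((n_bands, len(degs)), np.nan)
        )
        for k in range(n_bands):
            lo = int(k * dflt.BAND_HEIGHT)
            for d, r in zip(degs, banded[k]):
                row[f"cr_{lo:02d}m{_deg_token(d)}d_m_"] = r
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def write_metrics_csv(metrics_list, path) -> None:
    metrics_to_frame(metrics_list).to_csv(path, index=False)
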