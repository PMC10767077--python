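"""Procedural leaf-off tree point clouds with exact ground truth.

The generator emulates a subsampled single-tree TLS scan. A tree is built
entirely from cylinders - a tapered trunk, first-order branches, and a
crown realized as rings of thin "twig" cylinders inscribed in the crown
envelope plus a vertical leader shoot ending exactly at the tree top - and
every cylinder surface is sampled uniformly at a density of one point per
``point_spacing`` squared. Isotropic Gaussian sensor noise is then added
per coordinate and optional outlier points are planted well away from the
tree. Because every surface point lies on a cylinder that is also emitted
in the QSM table, the cloud and the cylinder model are mutually consistent:
the fit-quality check should flag essentially nothing beyond the noise
tail.

Crown envelopes: ``cylinder`` (constant elliptical cross-section),
``ellipsoid`` (full ellipsoid between crown start and tree top), ``cone``
(elliptical base at the crown start, apex at the tree top), or ``none`` (a
bare pole, exercising crownless degenerate behaviour). Twig rings follow
the envelope's horizontal cross-sections, with the maximal cross-section
(equator / base / any) always present so the specified directional crown
radii are realized in the cloud.

Every structural metric the measurement pipeline estimates is recorded
exactly in a :class:`GroundTruth`. Identical specs with identical seeds
produce bit-identical outputs; random streams are drawn in a fixed order
(trunk, crown rings, leader, branches, noise, outliers, intensity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import SyntheticSpecError
from .pointcloud_io import PointCloud, write_xyzi
from .qsm_graph import CylinderRecord, total_volume, write_cylinders
from .structure import direction_angles, max_crown_diameter

__all__ = [
    "CROWN_SHAPES",
    "SyntheticTreeSpec",
    "GroundTruth",
    "generate_tree",
    "make_fixture_suite",
]

CROWN_SHAPES = ("cylinder", "ellipsoid", "cone", "none")

_TWIG_RADIUS = 0.012  # crown twig-ring cylinder radius, m
_RING_SPACING = 0.75  # vertical spacing of twig rings, m
_MIN_RING_RADIUS = 0.05  # rings thinner than this are dropped, m
_LEADER_LENGTH = 0.8  # leader shoot length below the tree top, m


@dataclass(frozen=True)
class SyntheticTreeSpec:
    """Parameters of one synthetic tree.

    Defaults describe a typical mature urban street tree scanned leaf-off:
    40 cm DBH, 14 m tall, crown from 3 m, 2 m crown radius, sampled at the
    dataset's 2 cm subsampling density with 5 mm sensor noise.
    """

    seed: int = 0
    base: tuple = (0.0, 0.0, 0.0)
    trunk_radius: float = 0.20
    taper: float = 0.0  # fractional radius loss per meter of height
    tree_height: float = 14.0
    crown_start: float = 3.0
    crown_shape: str = "cylinder"
    crown_radius_x: float = 2.0
    crown_radius_y: float = 2.0
    branch_count: int = 8
    point_spacing: float = 0.02
    noise_sigma: float = 0.005
    outlier_count: int = 0
    outlier_offset: float = 1.0
    occlusion_sector: tuple | None = None  # (start_deg, end_deg), optional
    date: str = "2023-01-09"
    project_id: str = "synthetic"
    tree_id: str = "000001"

    def validate(self) -> None:
        if self.crown_shape not in CROWN_SHAPES:
            raise SyntheticSpecError(
                f"crown_shape must be one of {CROWN_SHAPES}, "
                f"got {self.crown_shape!r}"
            )
        if not self.trunk_radius > 0:
            raise SyntheticSpecError("trunk_radius must be positive")
        if not self.point_spacing > 0:
            raise SyntheticSpecError("point_spacing must be positive")
        if not self.tree_height > 0:
            raise SyntheticSpecError("tree_height must be positive")
        if self.crown_shape != "none" and not (
            0 < self.crown_start < self.tree_height
        ):
            raise SyntheticSpecError(
                "need 0 < crown_start < tree_height, got "
                f"{self.crown_start} vs {self.tree_height}"
            )
        if self.point_spacing > 0.5 * min(
            self.tree_height, 2 * np.pi * self.trunk_radius
        ):
            raise SyntheticSpecError(
                "point_spacing is larger than the tree's smallest dimension"
            )
        if self.crown_shape == "cylinder" and (
            min(self.crown_radius_x, self.crown_radius_y)
            <= self.trunk_radius
        ):
            raise SyntheticSpecError(
                "cylinder crown radius must exceed the trunk radius"
            )
        if self.taper < 0:
            raise SyntheticSpecError("taper must be >= 0")
        if self.taper * self.tree_height >= 1.0:
            raise SyntheticSpecError("taper removes the whole trunk radius")
        if self.noise_sigma < 0 or self.outlier_count < 0:
            raise SyntheticSpecError("noise/outlier settings must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact values of every structural metric for a synthetic tree."""

    location: np.ndarray
    dbh: float
    tree_height: float
    crown_start: float | None
    crown_radii: np.ndarray
    crown_diameter_max: float
    crown_projection_area: float
    total_volume_l: float
    n_outliers: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["location"] = np.asarray(self.location).tolist()
        d["crown_radii"] = np.asarray(self.crown_radii).tolist()
        return d


@dataclass(frozen=True)
class _Geom:
    """One generating cylinder before it is numbered into the table."""

    start: np.ndarray  # relative to the tree base
    axis: np.ndarray
    length: float
    radius: float
    branch_tag: int  # cylinders with equal tags form one chained branch
    branch_order: int
    attach_z: float  # trunk height the branch hangs off


def _ellipse_radius(rx: float, ry: float, theta) -> np.ndarray:
    """Center-to-boundary distance of an axis-aligned ellipse at azimuth theta."""
    theta = np.asarray(theta, dtype=float)
    return (rx * ry) / np.sqrt(
        (ry * np.cos(theta)) ** 2 + (rx * np.sin(theta)) ** 2
    )


def _n_for_area(area: float, spacing: float) -> int:
    return max(int(round(area / spacing**2)), 4)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _sample_cylinder_surface(geom: _Geom, spacing: float, rng) -> np.ndarray:
    """Uniform random points on the lateral surface of one cylinder."""
    n = _n_for_area(2 * np.pi * geom.radius * geom.length, spacing)
    axis = geom.axis
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(axis, helper))
    e2 = np.cross(axis, e1)
    t = rng.uniform(0.0, geom.length, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    return (
        geom.start
        + np.outer(t, axis)
        + geom.radius
        * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2))
    )


def _sample_trunk(spec: SyntheticTreeSpec, trunk_top: float, rng) -> np.ndarray:
    """Trunk surface with continuous taper: radius r(z) = r0 (1 - taper z)."""

    def radius_at(z):
        return spec.trunk_radius * (1.0 - spec.taper * z)

    mean_r = radius_at(trunk_top / 2.0)
    n = _n_for_area(2 * np.pi * mean_r * trunk_top, spec.point_spacing)
    z = rng.uniform(0.0, trunk_top, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    r = radius_at(z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _ring_cross_sections(spec: SyntheticTreeSpec) -> list[tuple[float, float]]:
    """Heights and radial scale factors (0..1 of the max cross-section) of
    the twig rings realizing the crown envelope."""
    cs, height = spec.crown_start, spec.tree_height
    depth = height - cs
    out: list[tuple[float, float]] = []
    if spec.crown_shape == "cylinder":
        n = max(int(round(depth / _RING_SPACING)), 2)
        for z in np.linspace(cs, height - 0.3 * min(1.0, depth / 2), n):
            out.append((float(z), 1.0))
    elif spec.crown_shape == "cone":
        n = max(int(round(depth / _RING_SPACING)), 2)
        for z in np.linspace(cs, height - 0.3 * min(1.0, depth / 2), n):
            out.append((float(z), float((height - z) / depth)))
    elif spec.crown_shape == "ellipsoid":
        c = depth / 2.0
        zc = cs + c
        n_rings = 17  # odd, so the equator ring is always present
        for theta in np.linspace(0.1, np.pi - 0.1, n_rings):
            out.append((float(zc + c * np.cos(theta)), float(np.sin(theta))))
    return out


def _crown_geoms(spec: SyntheticTreeSpec) -> list[_Geom]:
    """Twig rings (inscribed polygons of thin cylinders) plus the leader."""
    geoms: list[_Geom] = []
    if spec.crown_shape == "none":
        return geoms
    rx, ry = spec.crown_radius_x, spec.crown_radius_y
    tag = 0
    for z, scale in _ring_cross_sections(spec):
        srx, sry = scale * rx, scale * ry
        if min(srx, sry) < _MIN_RING_RADIUS:
            continue
        if z > spec.tree_height - 0.1:
            # keep twig tubes below the top; the leader realizes the height
            continue
        tag += 1
        perimeter = np.pi * (srx + sry)
        n_seg = max(int(round(perimeter / 0.3)), 8)
        t = np.linspace(0.0, 2 * np.pi, n_seg + 1)
        verts = np.column_stack(
            [srx * np.cos(t), sry * np.sin(t), np.full(n_seg + 1, z)]
        )
        for a, b in zip(verts[:-1], verts[1:]):
            seg = b - a
            length = float(np.linalg.norm(seg))
            geoms.append(
                _Geom(
                    start=a,
                    axis=_unit(seg),
                    length=length,
                    radius=_TWIG_RADIUS,
                    branch_tag=1000 + tag,
                    branch_order=2,
                    attach_z=z,
                )
            )
    # leader shoot: vertical twig ending exactly at the tree top
    length = min(_LEADER_LENGTH, 0.5 * (spec.tree_height - spec.crown_start))
    geoms.append(
        _Geom(
            start=np.array([0.0, 0.0, spec.tree_height - length]),
            axis=np.array([0.0, 0.0, 1.0]),
            length=length,
            radius=_TWIG_RADIUS,
            branch_tag=999,
            branch_order=1,
            attach_z=spec.tree_height - length,
        )
    )
    return geoms


def _envelope_radius(spec: SyntheticTreeSpec, z: float, theta: float) -> float:
    """Horizontal crown-envelope radius at height z in direction theta."""
    rx, ry = spec.crown_radius_x, spec.crown_radius_y
    cs, height = spec.crown_start, spec.tree_height
    r_eq = float(_ellipse_radius(rx, ry, theta))
    if z < cs or z > height:
        return 0.0
    if spec.crown_shape == "cylinder":
        return r_eq
    if spec.crown_shape == "cone":
        return r_eq * (height - z) / (height - cs)
    if spec.crown_shape == "ellipsoid":
        c = (height - cs) / 2.0
        zc = cs + c
        arg = 1.0 - ((z - zc) / c) ** 2
        return r_eq * np.sqrt(max(arg, 0.0))
    return 0.0


def _branch_geoms(
    spec: SyntheticTreeSpec, trunk_top: float, rng
) -> list[_Geom]:
    """First-order branches: straight cylinders from the trunk into the
    crown, kept inside the envelope."""
    geoms: list[_Geom] = []
    if spec.crown_shape == "none" or spec.branch_count == 0:
        return geoms
    cs, height = spec.crown_start, spec.tree_height
    z_hi = min(trunk_top, cs + 0.8 * (height - cs))
    for i in range(spec.branch_count):
        az = rng.uniform(0.0, 2 * np.pi)
        elev = rng.uniform(np.deg2rad(15.0), np.deg2rad(50.0))
        z0 = rng.uniform(cs + 0.05 * (height - cs), z_hi)
        direction = np.array(
            [
                np.cos(elev) * np.cos(az),
                np.cos(elev) * np.sin(az),
                np.sin(elev),
            ]
        )
        trunk_r = spec.trunk_radius * (1.0 - spec.taper * z0)
        start = np.array([trunk_r * np.cos(az), trunk_r * np.sin(az), z0])
        max_len = 0.0
        for frac in np.linspace(0.05, 1.0, 20):
            length = frac * (height - cs)
            tip = start + length * direction
            horiz = np.hypot(tip[0], tip[1])
            theta = np.arctan2(tip[1], tip[0])
            if (
                tip[2] >= height
                or horiz >= 0.95 * _envelope_radius(spec, tip[2], theta)
            ):
                break
            max_len = length
        if max_len < 0.2:
            continue
        radius = max(
            0.25
            * spec.trunk_radius
            * (1.0 - 0.5 * i / max(spec.branch_count, 1)),
            0.015,
        )
        geoms.append(
            _Geom(
                start=start,
                axis=direction,
                length=0.8 * max_len,
                radius=radius,
                branch_tag=i + 1,
                branch_order=1,
                attach_z=z0,
            )
        )
    return geoms


def _cylinder_records(
    spec: SyntheticTreeSpec, trunk_top: float, geoms: list[_Geom]
) -> list[CylinderRecord]:
    """Number the generating geometry into a QSM cylinder table.

    The trunk is split into ~1 m segments (branch 1, order 0) chained from
    the base; every other branch chains its own segments and hangs off the
    trunk segment at its attachment height.
    """
    base = np.asarray(spec.base, dtype=float)
    records: list[CylinderRecord] = []
    n_seg = max(int(np.ceil(trunk_top / 1.0)), 1)
    edges = np.linspace(0.0, trunk_top, n_seg + 1)

    def trunk_seg_of(z: float) -> int:
        return int(
            np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_seg - 1)
        )

    meta = dict(
        date=spec.date, project_id=spec.project_id, tree_id=spec.tree_id
    )
    for i in range(n_seg):
        lo, hi = edges[i], edges[i + 1]
        mid_r = spec.trunk_radius * (1.0 - spec.taper * (lo + hi) / 2.0)
        records.append(
            CylinderRecord(
                branch_id=1,
                branch_order=0,
                cylinder_id=i + 1,
                pos_in_branch=i + 1,
                parent_cyl_id=i,  # 0 for the first segment => root
                child_cyl_id=i + 2 if i + 1 < n_seg else 0,
                start=base + [0.0, 0.0, lo],
                axis=np.array([0.0, 0.0, 1.0]),
                length=float(hi - lo),
                radius=float(mid_r),
                added_virtual=0,
                **meta,
            )
        )
    next_id = n_seg + 1
    next_branch = 2
    by_tag: dict[int, list[_Geom]] = {}
    for g in geoms:
        by_tag.setdefault(g.branch_tag, []).append(g)
    for tag in sorted(by_tag):
        chain = by_tag[tag]
        branch_id = next_branch
        next_branch += 1
        prev_id = trunk_seg_of(min(chain[0].attach_z, trunk_top)) + 1
        for pos, g in enumerate(chain, start=1):
            records.append(
                CylinderRecord(
                    branch_id=branch_id,
                    branch_order=g.branch_order,
                    cylinder_id=next_id,
                    pos_in_branch=pos,
                    parent_cyl_id=prev_id,
                    child_cyl_id=next_id + 1 if pos < len(chain) else 0,
                    start=base + g.start,
                    axis=g.axis,
                    length=g.length,
                    radius=g.radius,
                    added_virtual=0,
                    **meta,
                )
            )
            prev_id = next_id
            next_id += 1
    return records


def _ground_truth(
    spec: SyntheticTreeSpec, records, n_directions: int = 72
) -> GroundTruth:
    theta = np.deg2rad(direction_angles(n_directions))
    if spec.crown_shape == "none":
        radii = np.full(n_directions, spec.trunk_radius)
        area = np.pi * spec.trunk_radius**2
        crown_start = None
    else:
        radii = _ellipse_radius(
            spec.crown_radius_x, spec.crown_radius_y, theta
        )
        area = np.pi * spec.crown_radius_x * spec.crown_radius_y
        crown_start = spec.crown_start
    dbh = 2.0 * spec.trunk_radius * (1.0 - spec.taper * 1.30)
    return GroundTruth(
        location=np.asarray(spec.base, dtype=float),
        dbh=float(dbh),
        tree_height=float(spec.tree_height),
        crown_start=crown_start,
        crown_radii=radii,
        crown_diameter_max=max_crown_diameter(radii),
        crown_projection_area=float(area),
        total_volume_l=total_volume(records),
        n_outliers=spec.outlier_count,
    )


def generate_tree(
    spec: SyntheticTreeSpec,
) -> tuple[PointCloud, list[CylinderRecord], GroundTruth]:
    """Generate one synthetic tree: cloud, cylinder table, ground truth.

    Planted outliers, if any, are the last ``spec.outlier_count`` points of
    the returned cloud.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.crown_shape == "none":
        trunk_top = spec.tree_height
    else:
        trunk_top = spec.crown_start + 0.5 * (
            spec.tree_height - spec.crown_start
        )

    parts = [_sample_trunk(spec, trunk_top, rng)]
    crown = _crown_geoms(spec)
    for g in crown:
        parts.append(_sample_cylinder_surface(g, spec.point_spacing, rng))
    if spec.crown_shape != "none":
        # exact leader tip, so the specified tree height is in the cloud
        parts.append(np.array([[0.0, 0.0, spec.tree_height]]))
    branches = _branch_geoms(spec, trunk_top, rng)
    for g in branches:
        parts.append(_sample_cylinder_surface(g, spec.point_spacing, rng))
    pts = np.vstack(parts)

    if spec.occlusion_sector is not None:
        lo, hi = (np.deg2rad(a) % (2 * np.pi) for a in spec.occlusion_sector)
        az = np.arctan2(pts[:, 1], pts[:, 0]) % (2 * np.pi)
        if lo <= hi:
            keep = ~((az >= lo) & (az < hi))
        else:
            keep = ~((az >= lo) | (az < hi))
        pts = pts[keep]

    if spec.noise_sigma > 0:
        pts = pts + rng.normal(0.0, spec.noise_sigma, pts.shape)

    pts = pts + np.asarray(spec.base, dtype=float)

    if spec.outlier_count > 0:
        center = pts.mean(axis=0)
        max_ext = np.linalg.norm(pts - center, axis=1).max()
        dirs = rng.normal(size=(spec.outlier_count, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        dist = (
            max_ext
            + spec.outlier_offset
            + rng.uniform(0.0, 2.0, spec.outlier_count)
        )
        pts = np.vstack([pts, center + dirs * dist[:, None]])

    intensity = rng.uniform(0.0, 100.0, pts.shape[0])
    cloud = PointCloud(pts, intensity)
    records = _cylinder_records(spec, trunk_top, crown + branches)
    truth = _ground_truth(spec, records)
    return cloud, records, truth


#: Seeded fixture specs used by the test battery: a crownless pole, the
#: default cylinder crown, an eccentric ellipsoid crown, a tapered trunk,
#: and a heavy-outlier case.
FIXTURE_SPECS: dict[str, SyntheticTreeSpec] = {
    "pole": SyntheticTreeSpec(
        seed=10, crown_shape="none", tree_height=8.0, trunk_radius=0.15,
        branch_count=0, tree_id="pole",
    ),
    "cylinder_crown": SyntheticTreeSpec(seed=11, tree_id="cylinder_crown"),
    "ellipsoid_crown": SyntheticTreeSpec(
        seed=12, crown_shape="ellipsoid", crown_radius_x=3.0,
        crown_radius_y=1.5, tree_height=12.0, tree_id="ellipsoid_crown",
    ),
    "tapered_trunk": SyntheticTreeSpec(
        seed=13, taper=0.03, trunk_radius=0.25, tree_id="tapered_trunk",
    ),
    "heavy_outliers": SyntheticTreeSpec(
        seed=14, outlier_count=40, outlier_offset=1.0,
        tree_id="heavy_outliers",
    ),
}


def make_fixture_suite(out_dir) -> dict[str, dict[str, Path]]:
    """Write the seeded fixture battery to ``out_dir``.

    For each fixture tree: ``<name>.txt`` (xyzi cloud), ``<name>_qsm.csv``
    (cylinder table) and ``<name>_truth.json`` (exact ground truth).
    Regeneration is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, Path]] = {}
    for name, spec in FIXTURE_SPECS.items():
        cloud, records, truth = generate_tree(spec)
        paths = {
            "cloud": out / f"{name}.txt",
            "qsm": out / f"{name}_qsm.csv",
            "truth": out / f"{name}_truth.json",
        }
        write_xyzi(cloud, paths["cloud"])
        write_cylinders(records, paths["qsm"])
        with open(paths["truth"], "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1)
        written[name] = paths
    return written
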