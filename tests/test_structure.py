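import numpy as np
import pytest

from canopymetrics.errors import MeasurementError
from canopymetrics.pointcloud_io import AffineTransform, PointCloud
from canopymetrics.structure import (
    crown_projection_area,
    crown_radii_72,
    crown_radii_by_height,
    estimate_crown_start,
    estimate_dbh,
    estimate_location,
    estimate_tree_height,
    max_crown_diameter,
    measure_tree,
    metrics_columns,
    metrics_to_frame,
)
from canopymetrics.synthetic import SyntheticTreeSpec, generate_tree


def trunk_rings(radius, z_lo, z_hi, center=(0.0, 0.0), dz=0.02, n_phi=64):
    """Noise-free points exactly on a vertical cylinder surface."""
    zs = np.arange(z_lo, z_hi, dz)
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    zz, pp = np.meshgrid(zs, phi)
    return np.column_stack(
        [
            center[0] + radius * np.cos(pp.ravel()),
            center[1] + radius * np.sin(pp.ravel()),
            zz.ravel(),
        ]
    )


def ring_cloud(radius, z_lo, z_hi, **kw):
    return PointCloud(trunk_rings(radius, z_lo, z_hi, **kw))


class TestLocation:
    def test_exact_trunk(self):
        cloud = ring_cloud(0.15, 0.2, 2.0, center=(3.0, 4.0))
        loc, fit = estimate_location(cloud)
        assert np.abs(loc - [3.0, 4.0, 0.2]).max() < 1e-6
        assert fit.radius == pytest.approx(0.15, abs=1e-9)

    def test_noisy_trunk_within_5mm(self, rng):
        xyz = trunk_rings(0.15, 0.0, 2.0, center=(3.0, 4.0))
        xyz += rng.normal(0, 0.005, xyz.shape)
        loc, _ = estimate_location(PointCloud(xyz))
        assert np.hypot(loc[0] - 3.0, loc[1] - 4.0) < 0.005

    def test_tiny_cloud_rejected(self):
        with pytest.raises(MeasurementError):
            estimate_location(PointCloud(np.random.default_rng(0).uniform(size=(5, 3))))


class TestDbh:
    def test_exact_cylinder(self):
        cloud = ring_cloud(0.20, 0.0, 3.0)
        dbh, _ = estimate_dbh(cloud, base_z=0.0)
        assert dbh == pytest.approx(0.40, abs=1e-6)

    def test_mean_error_under_1cm_with_noise(self):
        errors = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            xyz = trunk_rings(0.20, 1.2, 1.4)
            xyz += rng.normal(0, 0.005, xyz.shape)
            xyz = np.vstack([xyz, [[0.2, 0, 0.0]]])  # set the base
            dbh, _ = estimate_dbh(PointCloud(xyz), base_z=0.0)
            errors.append(abs(dbh - 0.40))
        assert np.mean(errors) <= 0.01

    def test_truncated_cloud_rejected(self):
        # segmentation lost the lower trunk: nothing near breast height
        cloud = ring_cloud(0.2, 1.5, 3.0)
        with pytest.raises(MeasurementError):
            estimate_dbh(cloud, base_z=0.0)


class TestCrownStart:
    def test_trunk_with_crown_detected_near_three_meters(self):
        trunk = trunk_rings(0.15, 0.0, 3.0)
        crown = trunk_rings(0.7, 3.0, 5.0)
        cloud = PointCloud(np.vstack([trunk, crown]))
        cs = estimate_crown_start(
            cloud, base_z=0.0, initial_radius=0.15, tree_height=5.0,
            scan_cap=0.9,
        )
        assert cs is not None
        assert 2.9 <= cs <= 3.1

    def test_constant_radius_pole_not_found(self):
        cloud = ring_cloud(0.15, 0.0, 6.0)
        cs = estimate_crown_start(
            cloud, base_z=0.0, initial_radius=0.15, tree_height=6.0
        )
        assert cs is None

    def test_thirteen_percent_step_below_threshold(self):
        lower = trunk_rings(0.15, 0.0, 3.0)
        upper = trunk_rings(0.17, 3.0, 6.0)  # 13% < 20%
        cloud = PointCloud(np.vstack([lower, upper]))
        cs = estimate_crown_start(
            cloud, base_z=0.0, initial_radius=0.15, tree_height=6.0
        )
        assert cs is None


class TestTreeHeight:
    def test_vertical_extent(self):
        cloud = PointCloud(np.array([[0, 0, 0.0], [1, 1, 12.5], [0, 1, 3.0]]))
        assert estimate_tree_height(cloud) == pytest.approx(12.5)

    def test_flat_plane_has_zero_height(self, rng):
        xy = rng.uniform(0, 1, (50, 2))
        cloud = PointCloud(np.column_stack([xy, np.full(50, 2.0)]))
        assert estimate_tree_height(cloud) == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(MeasurementError):
            estimate_tree_height(PointCloud(np.zeros((1, 3))))


class TestCrownRadii:
    def test_cylindrical_crown_all_directions(self):
        crown = trunk_rings(2.0, 3.0, 8.0, dz=0.05, n_phi=720)
        radii = crown_radii_72(
            PointCloud(crown), np.array([0.0, 0.0, 0.0]), 3.0, base_z=0.0
        )
        assert radii.shape == (72,)
        assert np.all(radii >= 1.98) and np.all(radii <= 2.0 + 1e-9)

    def test_elliptical_crown_axis_radii(self):
        theta = np.linspace(0, 2 * np.pi, 3000, endpoint=False)
        ellipse = np.column_stack(
            [3.0 * np.cos(theta), 1.0 * np.sin(theta), np.full_like(theta, 5.0)]
        )
        radii = crown_radii_72(
            PointCloud(ellipse), np.zeros(3), 4.0, base_z=0.0
        )
        assert radii[0] == pytest.approx(3.0, rel=0.02)  # 0 deg
        assert radii[18] == pytest.approx(1.0, rel=0.02)  # 90 deg

    def test_empty_direction_gives_zero(self):
        # points only on the +x side: the -x direction (180 deg) sees nothing
        half = np.array([[1.0, 0.0, 5.0], [1.5, 0.1, 5.0], [2.0, -0.1, 5.0]])
        radii = crown_radii_72(PointCloud(half), np.zeros(3), 4.0, base_z=0.0)
        assert radii[36] == 0.0
        assert radii[0] > 0


class TestMaxCrownDiameter:
    def test_uniform_radii(self):
        assert max_crown_diameter(np.full(72, 2.0)) == pytest.approx(4.0)

    def test_all_zero(self):
        assert max_crown_diameter(np.zeros(72)) == 0.0

    def test_ellipse_major_axis(self):
        theta = np.deg2rad(np.arange(72) * 5.0)
        radii = 3.0 / np.sqrt(np.cos(theta) ** 2 + 9 * np.sin(theta) ** 2)
        assert max_crown_diameter(radii) == pytest.approx(6.0, rel=0.02)


class TestCrownProjectionArea:
    def test_square_footprint(self, rng):
        xy = rng.uniform(-2, 2, size=(20000, 2))
        crown = np.column_stack([xy, rng.uniform(4, 8, 20000)])
        area = crown_projection_area(PointCloud(crown), 4.0, base_z=0.0)
        assert area == pytest.approx(16.0, rel=0.01)

    def test_disc_footprint(self):
        crown = trunk_rings(2.0, 4.0, 5.0, dz=0.1, n_phi=1000)
        area = crown_projection_area(PointCloud(crown), 4.0, base_z=0.0)
        assert area == pytest.approx(np.pi * 4.0, rel=0.01)

    def test_two_crown_points_rejected(self):
        cloud = PointCloud(np.array([[0, 0, 5.0], [1, 0, 5.0], [0, 0, 0.0]]))
        with pytest.raises(MeasurementError):
            crown_projection_area(cloud, 4.0, base_z=0.0)


class TestCrownRadiiByHeight:
    def test_short_tree_upper_bands_empty(self):
        cloud = ring_cloud(0.2, 0.0, 5.0)
        banded = crown_radii_by_height(cloud, np.zeros(3), base_z=0.0)
        assert banded.shape == (15, 72)
        assert np.all(banded[3:] == 0.0)
        assert np.all(banded[0] > 0)

    def test_trunk_and_crown_bands(self):
        trunk = trunk_rings(0.15, 0.0, 4.0)
        crown = trunk_rings(2.0, 4.0, 7.0, dz=0.05, n_phi=720)
        cloud = PointCloud(np.vstack([trunk, crown]))
        banded = crown_radii_by_height(cloud, np.zeros(3), base_z=0.0)
        assert np.allclose(banded[0], 0.15, atol=0.01)
        assert np.allclose(banded[2], 2.0, atol=0.05)


class TestMeasureTree:
    def test_end_to_end_parameter_recovery(self, default_tree, default_tree_metrics):
        _, _, _, truth = default_tree
        m = default_tree_metrics
        assert abs(m.dbh - truth.dbh) <= 0.01
        assert abs(m.tree_height - truth.tree_height) <= 0.02
        assert abs(m.crown_start_height - truth.crown_start) <= 0.15
        rel = np.abs(m.crown_radii - truth.crown_radii) / truth.crown_radii
        assert rel.max() <= 0.02
        assert m.total_volume_l == pytest.approx(truth.total_volume_l)
        assert not m.failures

    def test_opposite_radius_invariant_holds(self, default_tree_metrics):
        m = default_tree_metrics
        opposite = np.roll(m.crown_radii, -36)
        assert m.crown_diameter_max == pytest.approx(
            float((m.crown_radii + opposite).max())
        )

    def test_projection_area_bounds(self, default_tree_metrics):
        m = default_tree_metrics
        assert m.crown_projection_area <= np.pi * m.crown_radii.max() ** 2

    def test_pole_reports_missing_crown_start(self):
        spec = SyntheticTreeSpec(
            seed=10, crown_shape="none", tree_height=8.0, trunk_radius=0.15,
            branch_count=0, point_spacing=0.03,
        )
        cloud, _, _ = generate_tree(spec)
        m = measure_tree(cloud)
        assert m.crown_start_height is None
        assert "crown_start" in m.failures
        assert m.crown_fallback_whole_cloud
        # fallback metrics are computed over the whole cloud (the trunk)
        assert m.crown_radii is not None
        assert np.nanmax(m.crown_radii) == pytest.approx(0.15, abs=0.02)

    def test_identity_transform_copies_location(self, small_tree):
        _, cloud, _, _ = small_tree
        m = measure_tree(cloud, transform=AffineTransform.identity())
        np.testing.assert_allclose(m.location_global, m.location)

    def test_translation_invariance(self, small_tree):
        _, cloud, _, _ = small_tree
        base = measure_tree(cloud)
        shift = np.array([250.0, -120.0, 0.0])
        moved = measure_tree(PointCloud(cloud.xyz + shift, cloud.intensity))
        assert moved.dbh == pytest.approx(base.dbh, abs=1e-6)
        assert moved.tree_height == pytest.approx(base.tree_height, abs=1e-6)
        assert moved.crown_start_height == pytest.approx(
            base.crown_start_height, abs=1e-6
        )
        np.testing.assert_allclose(
            moved.crown_radii, base.crown_radii, atol=1e-6
        )
        np.testing.assert_allclose(
            moved.location, base.location + shift, atol=1e-6
        )

    def test_adding_crown_points_never_shrinks_radii(self, small_tree, rng):
        _, cloud, _, _ = small_tree
        loc, _ = estimate_location(cloud)
        radii = crown_radii_72(cloud, loc, 2.5)
        area = crown_projection_area(cloud, 2.5, base_z=float(loc[2]))
        extra = rng.uniform([-1, -1, 3.0], [1, 1, 6.0], size=(500, 3))
        bigger = PointCloud(np.vstack([cloud.xyz, extra]))
        radii2 = crown_radii_72(bigger, loc, 2.5)
        area2 = crown_projection_area(bigger, 2.5, base_z=float(loc[2]))
        assert np.all(radii2 >= radii - 1e-12)
        assert area2 >= area - 1e-12

    def test_empty_cloud_aborts(self):
        with pytest.raises(MeasurementError):
            measure_tree(PointCloud.empty())


class TestMetricsTable:
    def test_column_layout(self):
        cols = metrics_columns()
        assert cols[:4] == ["date", "projectID", "treeID", "botanical.name"]
        assert "DBH(m)" in cols and "totalVolume(L)" in cols
        assert cols.count("crown0_00d_m_") == 1
        assert "crown3_55d_m_" in cols
        assert "cr_00m0_00d_m_" in cols and "cr_28m3_55d_m_" in cols
        assert len(cols) == 16 + 72 + 15 * 72

    def test_single_row_frame(self, default_tree_metrics):
        frame = metrics_to_frame(default_tree_metrics)
        assert frame.shape == (1, 16 + 72 + 15 * 72)
        assert frame.loc[0, "DBH(m)"] == default_tree_metrics.dbh
        assert (
            frame.loc[0, "crown0_00d_m_"]
            == default_tree_metrics.crown_radii[0]
        )
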