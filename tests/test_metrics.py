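"""Morphometry: PCA shape closed forms, outlier removal, size classes."""

import math

import numpy as np
import pytest

from clustorm.metrics import (
    SizeBinning,
    SizeClass,
    measure_cluster,
    pca_shape,
    remove_outliers,
    size_distribution,
)


class TestPcaShape:
    def test_single_point_has_zero_extents(self):
        _, _, extents = pca_shape([[5.0, 7.0]])
        assert extents == (0.0, 0.0)

    def test_collinear_segment_closed_form(self):
        pts = np.column_stack([np.linspace(0, 100, 11), np.zeros(11)])
        centroid, axes, (maj, mi) = pca_shape(pts)
        assert np.allclose(centroid, [50.0, 0.0])
        assert np.allclose(np.abs(axes[0]), [1.0, 0.0])
        assert maj == pytest.approx(100.0)
        assert mi == pytest.approx(0.0, abs=1e-9)

    def test_dense_circle_diameter_recovers_2r(self):
        # 2000 points uniform on a circle of radius r: both extents -> 2r
        rng = np.random.default_rng(5)
        r = 250.0
        theta = rng.uniform(0, 2 * np.pi, 2000)
        pts = r * np.column_stack([np.cos(theta), np.sin(theta)])
        _, _, (maj, mi) = pca_shape(pts)
        mean_diam = (maj + mi) / 2
        assert abs(mean_diam - 2 * r) / (2 * r) < 0.02

    def test_axes_orthonormal_and_major_first(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, [30.0, 5.0], size=(200, 2))
        _, axes, (maj, mi) = pca_shape(pts)
        assert np.allclose(axes @ axes.T, np.eye(2), atol=1e-12)
        assert maj >= mi

    def test_isotropic_tiebreak_prefers_x(self):
        pts = np.array([[1.0, 0], [-1, 0], [0, 1.0], [0, -1.0]])
        _, axes, _ = pca_shape(pts)
        assert np.allclose(axes[0], [1.0, 0.0])


class TestRemoveOutliers:
    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(50, 2))
        out = remove_outliers(pts, math.inf)
        assert np.array_equal(out, pts)

    def test_far_point_removed(self):
        rng = np.random.default_rng(2)
        blob = rng.normal(0, 10, size=(100, 2))
        far = np.array([[200.0, 0.0]])  # 20 blob-sds away
        out = remove_outliers(np.vstack([blob, far]), 2.5)
        assert len(out) <= 100
        assert not np.any(np.all(out == far, axis=1))

    def test_tight_gaussian_mostly_survives(self):
        # under normality a 3-sd cut keeps ~99.7% per axis
        rng = np.random.default_rng(3)
        kept = []
        for _ in range(50):
            pts = rng.normal(0, 8, size=(200, 2))
            kept.append(len(remove_outliers(pts, 3.0)) / 200)
        assert np.mean(kept) >= 0.98

    def test_never_empties_below_one_point(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        out = remove_outliers(pts, 0.0001)
        assert len(out) >= 1


class TestSizeClasses:
    BINNING = SizeBinning()

    @pytest.mark.parametrize(
        "diameter, expected",
        [
            (0.0, SizeClass.SUB_SMALL),
            (19.9, SizeClass.SUB_SMALL),
            (20.0, SizeClass.SMALL),
            (99.9, SizeClass.SMALL),
            (100.0, SizeClass.MEDIUM),
            (299.9, SizeClass.MEDIUM),
            (300.0, SizeClass.LARGE),
            (499.9, SizeClass.LARGE),
            (500.0, SizeClass.VERY_LARGE),
            (10000.0, SizeClass.VERY_LARGE),
        ],
    )
    def test_halfopen_bin_assignment(self, diameter, expected):
        assert self.BINNING.classify(diameter) is expected

    def test_every_diameter_maps_to_exactly_one_class(self):
        rng = np.random.default_rng(8)
        for d in rng.uniform(0, 1500, 500):
            assert self.BINNING.classify(float(d)) in SizeClass

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            SizeBinning((100.0, 20.0, 300.0, 500.0))


class TestMeasureCluster:
    BINNING = SizeBinning()

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 40, size=(60, 2))
        c1 = measure_cluster(pts, self.BINNING)
        c2 = measure_cluster(pts * 3.0, self.BINNING)
        assert c2.mean_diameter_nm == pytest.approx(3.0 * c1.mean_diameter_nm)
        assert c2.n_localizations == c1.n_localizations

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 40, size=(60, 2))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        c1 = measure_cluster(pts, self.BINNING)
        c2 = measure_cluster(pts @ rot.T + [500, -300], self.BINNING)
        assert c2.mean_diameter_nm == pytest.approx(c1.mean_diameter_nm)

    def test_extent_ordering_and_inner_density(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            pts = rng.normal(0, rng.uniform(5, 100, 2), size=(30, 2))
            c = measure_cluster(pts, self.BINNING)
            assert c.extent_major_nm >= c.extent_minor_nm >= 0
            assert c.n_localizations == 30
            assert c.mean_diameter_nm == pytest.approx(
                (c.extent_major_nm + c.extent_minor_nm) / 2
            )

    def test_monomer_scale_microcluster(self):
        # a ~7-member micro-cluster with ~23 nm footprint straddles the
        # sub-small/small boundary; n_localizations must stay 7 either way
        rng = np.random.default_rng(10)
        pts = rng.normal(0, 8.0, size=(7, 2))
        c = measure_cluster(pts, self.BINNING)
        assert c.n_localizations == 7
        assert c.size_class in (SizeClass.SUB_SMALL, SizeClass.SMALL)


class TestSizeDistribution:
    BINNING = SizeBinning()

    def _cluster_with_diameter(self, d):
        half = d / 2
        pts = np.array([[-half, 0.0], [half, 0.0], [0.0, -half], [0.0, half]])
        # extents are (d, d) so mean diameter is exactly d
        return measure_cluster(pts, self.BINNING, outlier_sd=math.inf)

    def test_empty_input_gives_zero_histogram(self):
        hist = size_distribution([], self.BINNING)
        assert all(v == 0 for v in hist.values())

    def test_one_cluster_per_bin(self):
        clusters = [self._cluster_with_diameter(d) for d in (25, 150, 350, 600)]
        hist = size_distribution(clusters, self.BINNING)
        assert (hist["small"], hist["medium"], hist["large"], hist["very_large"]) == (
            1,
            1,
            1,
            1,
        )
        assert hist["sub_small"] == 0

    def test_histogram_matches_ground_truth_binning(self, aggregate_config):
        """Pipeline size histogram matches ground-truth diameters binned the
        same way, within assignment error at the bin edges."""
        from clustorm.clustering import ClusteringParams, dbscan_cluster
        from clustorm.metrics import measure_clusters
        from clustorm.synthetic import generate_field

        fld, truth = generate_field(aggregate_config)
        labeling = dbscan_cluster(fld, ClusteringParams(eps_nm=30, min_pts=5))
        clusters = measure_clusters(fld.xy, labeling.labels, self.BINNING)
        big = [c for c in clusters if c.n_localizations >= 20]
        got = size_distribution(big, self.BINNING)
        want = {"small": 0, "medium": 0, "large": 0, "very_large": 0}
        for d in truth.aggregate_diameters_nm:
            want[self.BINNING.classify(float(d)).value.lower()] += 1
        for k in want:
            assert abs(got[k] - want[k]) <= 1, (k, got, want)
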