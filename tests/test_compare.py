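"""Density filter, free-fraction accounting, monomer matching and the
group-statistics layer."""

import math

import numpy as np
import pytest

from clustorm.clustering import ClusteringParams, ClusterLabeling, dbscan_cluster
from clustorm.compare import (
    ComparisonDesign,
    DensityFilterPolicy,
    FieldClusters,
    MissingReferenceError,
    MonomerReference,
    apply_density_filter,
    clusters_per_region,
    conservation_holds,
    free_fraction,
    group_compare,
    monomer_match_fraction,
    one_way_anova,
    summarize_field,
    ttest,
    two_way_anova,
)
from clustorm.io import FieldMetadata, LocalizationField, Rect
from clustorm.metrics import SizeBinning, SizeClass, measure_clusters
from clustorm.synthetic import generate_field

import pandas as pd

BINNING = SizeBinning()


def _toy_record(densities, condition, day="d0", diameter=60.0, subject="m0"):
    """A FieldClusters whose clusters have the given inner densities.

    Each cluster is a ring of `density` points spanning `diameter` nm so the
    measured mean diameter is aggregate-scale (not sub-small).
    """
    pts = []
    labels = []
    for cid, dens in enumerate(densities):
        theta = np.linspace(0, 2 * np.pi, dens, endpoint=False)
        ring = 5000 * cid + (diameter / 2) * np.column_stack(
            [np.cos(theta), np.sin(theta)]
        )
        pts.append(ring + 1000.0)
        labels.extend([cid] * dens)
    xy = np.concatenate(pts) if pts else np.empty((0, 2))
    labels = np.asarray(labels, dtype=int)
    roi = Rect(0, 0, max(10000, 5000 * len(densities)), 10000)
    fld = LocalizationField(
        xy[:, 0],
        xy[:, 1],
        np.zeros(len(xy), dtype=int),
        roi,
        metadata=FieldMetadata(subject=subject, condition=condition, imaging_day=day),
    )
    clusters = measure_clusters(xy, labels, BINNING, outlier_sd=math.inf)
    return FieldClusters(fld, ClusterLabeling(labels, len(densities)), clusters)


class TestDensityFilter:
    POLICY = DensityFilterPolicy(reference_condition="placebo", threshold_fraction=0.10)

    def test_toy_case_excludes_one_cluster_and_moves_locs_to_free(self):
        ref = _toy_record([100, 100], "placebo")
        trt = _toy_record([5, 120], "treated")
        thresholds = apply_density_filter([ref, trt], self.POLICY)
        assert thresholds == {"d0": pytest.approx(10.0)}
        assert [c.retained for c in ref.clusters] == [True, True]
        assert [c.retained for c in trt.clusters] == [False, True]
        # the 5 excluded localizations now count as free
        assert free_fraction(trt) == pytest.approx(100.0 * 5 / 125)

    def test_boundary_is_strict_less_than(self):
        ref = _toy_record([100, 100], "placebo")
        trt = _toy_record([10], "treated")  # exactly 10% of the mean
        apply_density_filter([ref, trt], self.POLICY)
        assert trt.clusters[0].retained

    def test_missing_reference_day_is_an_error_naming_the_day(self):
        trt = _toy_record([50], "treated", day="d7")
        with pytest.raises(MissingReferenceError, match="d7"):
            apply_density_filter([trt], self.POLICY)

    def test_reference_mean_is_per_day_never_pooled(self):
        ref0 = _toy_record([100], "placebo", day="d0")
        ref1 = _toy_record([1000], "placebo", day="d1")
        trt0 = _toy_record([50], "treated", day="d0")
        trt1 = _toy_record([50], "treated", day="d1")
        apply_density_filter([ref0, ref1, trt0, trt1], self.POLICY)
        assert trt0.clusters[0].retained  # 50 >= 10
        assert not trt1.clusters[0].retained  # 50 < 100

    def test_idempotent(self):
        ref = _toy_record([100, 100, 4], "placebo")
        trt = _toy_record([5, 120], "treated")
        recs = [ref, trt]
        t1 = apply_density_filter(recs, self.POLICY)
        state1 = [[c.retained for c in r.clusters] for r in recs]
        t2 = apply_density_filter(recs, self.POLICY)
        state2 = [[c.retained for c in r.clusters] for r in recs]
        assert t1 == t2
        assert state1 == state2

    def test_retained_count_monotone_in_threshold(self):
        rng = np.random.default_rng(21)
        densities = rng.integers(3, 200, size=12).tolist()
        counts = []
        for frac in (0.05, 0.1, 0.2, 0.4, 0.8):
            rec = _toy_record(densities, "placebo")
            apply_density_filter(
                [rec], DensityFilterPolicy("placebo", threshold_fraction=frac)
            )
            counts.append(sum(c.retained for c in rec.clusters))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFreeFraction:
    def test_all_in_one_retained_cluster_gives_zero(self):
        rec = _toy_record([50], "placebo")
        assert free_fraction(rec) == 0.0

    def test_no_retained_clusters_gives_hundred(self):
        rec = _toy_record([50], "placebo")
        rec.clusters[0].retained = False
        assert free_fraction(rec) == 100.0

    def test_empty_field_is_no_data_not_zero(self):
        rec = _toy_record([], "placebo")
        assert free_fraction(rec) is None

    def test_subsmall_clusters_count_as_free_by_default(self):
        rec = _toy_record([40, 10], "placebo", diameter=60.0)
        # shrink the second cluster to sub-small scale
        small = _toy_record([10], "placebo", diameter=10.0)
        rec.clusters[1] = small.clusters[0]
        assert rec.clusters[1].size_class is SizeClass.SUB_SMALL
        assert free_fraction(rec) == pytest.approx(100.0 * 10 / 50)
        assert free_fraction(rec, count_subsmall_as_free=False) == 0.0

    def test_recovers_ground_truth_on_synthetic_field(self, aggregate_config):
        fld, truth = generate_field(aggregate_config)
        lab = dbscan_cluster(fld, ClusteringParams(eps_nm=30, min_pts=5))
        clusters = measure_clusters(fld.xy, lab.labels, BINNING)
        est = free_fraction(FieldClusters(fld, lab, clusters))
        assert est == pytest.approx(truth.free_fraction_pct, abs=5.0)


class TestConservation:
    def test_holds_after_clustering_and_filtering(self, aggregate_config):
        fld, _ = generate_field(aggregate_config)
        lab = dbscan_cluster(fld, ClusteringParams(eps_nm=30, min_pts=5))
        clusters = measure_clusters(fld.xy, lab.labels, BINNING)
        fc = FieldClusters(fld, lab, clusters)
        fc.field.metadata = FieldMetadata(condition="placebo", imaging_day="d0")
        assert conservation_holds(fc)
        apply_density_filter([fc], DensityFilterPolicy("placebo"))
        assert conservation_holds(fc)
        # clustered + free = total, with excluded clusters counted free
        total = len(fc.field)
        clustered = fc.n_clustered_localizations()
        pf = free_fraction(fc)
        assert clustered + round(pf * total / 100) == total


class TestClustersPerRegion:
    def test_zero_clusters(self):
        rec = _toy_record([], "placebo")
        assert clusters_per_region(rec) == 0.0

    def test_arithmetic_and_homogeneity(self):
        roi40 = Rect(0, 0, 8000, 5000)  # 40 um^2
        assert clusters_per_region(10, roi40) == pytest.approx(5.0)
        roi80 = Rect(0, 0, 8000, 10000)
        assert clusters_per_region(10, roi80) == pytest.approx(2.5)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            clusters_per_region(1, Rect(0, 0, 0, 100))


class TestMonomerMatch:
    REF = MonomerReference(sd_diameter_nm=6.0, sd_locs=2.5, envelope_k=2.0)

    def test_far_population_matches_zero(self):
        assert monomer_match_fraction([400.0] * 5, [1000] * 5, self.REF) == 0.0

    def test_infinite_envelope_matches_all(self):
        ref = MonomerReference(envelope_k=math.inf)
        assert monomer_match_fraction([1.0, 500.0], [1, 900], ref) == 1.0

    def test_empty_population_is_no_data(self):
        assert monomer_match_fraction([], [], self.REF) is None

    def test_reference_like_population_matches_at_envelope_coverage(self):
        # population drawn from the reference law itself: with k=2 the
        # two-dimensional envelope keeps the large majority
        rng = np.random.default_rng(31)
        d = rng.normal(23.0, 6.0, 3000)
        n = rng.poisson(7, 3000)
        frac = monomer_match_fraction(d, n, self.REF)
        assert 0.80 <= frac <= 0.98


class TestGroupStats:
    def test_identical_groups_give_t_zero_p_one(self):
        t, _, p = ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "pooled")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_pooled_t_closed_form(self):
        # hand computation: means 2 vs 5, pooled sd 1, se = sqrt(2/3)
        t, dof, p = ttest([1, 2, 3], [4, 5, 6], "pooled")
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert dof == 4
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_too_few_replicates_refused(self):
        with pytest.raises(ValueError):
            ttest([1.0], [2.0, 3.0])

    def test_one_way_anova_two_equal_groups_matches_t(self):
        f, p = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert f == pytest.approx(3.674**2, rel=1e-3)

    def test_two_way_anova_detects_main_effect(self):
        rng = np.random.default_rng(41)
        rows = []
        for a in ("x", "y"):
            for b in ("u", "v"):
                for _ in range(6):
                    rows.append(
                        {"fa": a, "fb": b, "y": rng.normal(3.0 if a == "x" else 6.0, 1)}
                    )
        tab = two_way_anova(pd.DataFrame(rows), "y", "fa", "fb")
        assert tab.loc["C(_fa)", "PR(>F)"] < 0.01
        assert tab.loc["C(_fb)", "PR(>F)"] > 0.05

    def test_group_compare_averages_fields_per_subject(self):
        rows = []
        for cond, base in (("placebo", 10.0), ("treated", 20.0)):
            for s in range(3):
                for f in range(4):
                    rows.append(
                        {
                            "subject": f"{cond}{s}",
                            "condition": cond,
                            "pct_free": base + s + 0.01 * f,
                            "mean_inner_density": 100.0 - base + s,
                        }
                    )
        report = group_compare(pd.DataFrame(rows), ComparisonDesign(test="pooled"))
        g = report["metrics"]["pct_free"]["groups"]
        assert g["placebo"]["n"] == 3  # subjects, not fields
        assert g["placebo"]["mean"] == pytest.approx(11.015)
        pw = report["metrics"]["pct_free"]["pairwise"][0]
        assert pw["p_bonferroni"] >= pw["p"]
        assert pw["significant"]

    def test_group_with_single_subject_refused(self):
        df = pd.DataFrame(
            [
                {"subject": "a", "condition": "placebo", "pct_free": 1.0},
                {"subject": "b", "condition": "treated", "pct_free": 2.0},
                {"subject": "c", "condition": "treated", "pct_free": 3.0},
            ]
        )
        with pytest.raises(ValueError, match="replicates"):
            group_compare(df, ComparisonDesign(metrics=("pct_free",)))


def test_summarize_field_shape(aggregate_config):
    fld, _ = generate_field(aggregate_config)
    lab = dbscan_cluster(fld, ClusteringParams(eps_nm=30, min_pts=5))
    clusters = measure_clusters(fld.xy, lab.labels, BINNING)
    row = summarize_field(FieldClusters(fld, lab, clusters), BINNING)
    assert row["n_localizations"] == len(fld)
    assert 0 <= row["pct_free"] <= 100
    assert row["n_clusters_retained"] >= row["n_small"]
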