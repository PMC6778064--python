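"""Condition comparison: density filtering, free-fraction accounting,
monomer-reference matching and group statistics.

The central rule is the condition-matched inner-density filter: on each
imaging day, the mean inner density (localizations per cluster) of the
reference condition's aggregate-scale clusters defines a threshold; clusters
of *either* condition measured that day with strictly less than 10% of that
mean are excluded, and their localizations are returned to the free
(unclustered) population.  This guards against sparse, homogeneous
localization carpets registering as aggregates.

Accounting conventions (documented, config-exposed):

* sub-small micro-clusters (< 20 nm apparent diameter — single-protein scale)
  are counted with the free population, because the study's "non-clustered"
  species are themselves detectable micro-assemblies;
* the free fraction is localization-weighted: % of a field's localizations
  not in a retained aggregate-scale cluster;
* the biological unit for group statistics is the subject (mouse): field
  summaries are averaged per subject before any test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import FREE, ClusterLabeling
from .io import LocalizationField, Rect
from .metrics import Cluster, SizeBinning, SizeClass, size_distribution


@dataclass
class FieldClusters:
    """A field together with its cluster partition and morphometry."""

    field: LocalizationField
    labeling: ClusterLabeling
    clusters: List[Cluster]

    @property
    def condition(self) -> str:
        return self.field.metadata.condition

    @property
    def imaging_day(self) -> str:
        return self.field.metadata.imaging_day

    @property
    def subject(self) -> str:
        return self.field.metadata.subject

    def counted_clusters(self, count_subsmall_as_free: bool = True) -> List[Cluster]:
        """Retained clusters counted as aggregates."""
        return [
            c
            for c in self.clusters
            if c.retained
            and not (count_subsmall_as_free and c.size_class is SizeClass.SUB_SMALL)
        ]

    def n_clustered_localizations(self, count_subsmall_as_free: bool = True) -> int:
        return sum(
            c.n_localizations for c in self.counted_clusters(count_subsmall_as_free)
        )


@dataclass(frozen=True)
class DensityFilterPolicy:
    """The 10%-of-reference-mean inner-density exclusion rule, per day."""

    reference_condition: str = "placebo"
    threshold_fraction: float = 0.10
    grouping_key: str = "imaging_day"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in (0, 1)")


class MissingReferenceError(ValueError):
    """An imaging-day group lacks reference-condition clusters."""


def apply_density_filter(
    records: Sequence[FieldClusters],
    policy: DensityFilterPolicy,
    count_subsmall_as_free: bool = True,
) -> Dict[str, float]:
    """Apply the per-day inner-density filter in place.

    For every imaging day, the mean inner density is computed over *all* the
    reference condition's aggregate-scale clusters of that day (regardless of
    any previous filtering, which makes the operation idempotent); clusters
    with strictly fewer localizations than ``threshold_fraction`` times that
    mean are marked not retained.  Their localizations count as free from
    then on.  Returns the per-day thresholds.
    """
    by_day: Dict[str, List[FieldClusters]] = {}
    for rec in records:
        by_day.setdefault(rec.imaging_day, []).append(rec)

    thresholds: Dict[str, float] = {}
    for day, recs in by_day.items():
        ref_densities = [
            c.n_localizations
            for rec in recs
            if rec.condition == policy.reference_condition
            for c in rec.clusters
            if not (count_subsmall_as_free and c.size_class is SizeClass.SUB_SMALL)
        ]
        if not ref_densities:
            raise MissingReferenceError(
                f"imaging day {day!r} has no {policy.reference_condition!r} "
                "clusters to derive a density threshold from"
            )
        threshold = policy.threshold_fraction * float(np.mean(ref_densities))
        thresholds[day] = threshold
        for rec in recs:
            for c in rec.clusters:
                if count_subsmall_as_free and c.size_class is SizeClass.SUB_SMALL:
                    continue
                # "less than" is strict: a cluster exactly at the threshold stays
                c.retained = c.n_localizations >= threshold
    return thresholds


def free_fraction(
    fc: FieldClusters, count_subsmall_as_free: bool = True
) -> Optional[float]:
    """Percentage of the field's localizations in the free population.

    Free = DBSCAN noise + localizations of density-excluded clusters (+ those
    of sub-small micro-clusters under the default accounting).  ``None``
    marks an empty field (no data), never 0.
    """
    total = len(fc.field)
    if total == 0:
        return None
    clustered = fc.n_clustered_localizations(count_subsmall_as_free)
    return 100.0 * (total - clustered) / total


def clusters_per_region(
    fc_or_count, roi: Optional[Rect] = None, count_subsmall_as_free: bool = True
) -> float:
    """Retained aggregate-scale clusters per 20 µm² of ROI."""
    if isinstance(fc_or_count, FieldClusters):
        n = len(fc_or_count.counted_clusters(count_subsmall_as_free))
        roi = fc_or_count.field.roi
    else:
        n = int(fc_or_count)
        if roi is None:
            raise ValueError("roi required when passing a bare count")
    area = roi.area_um2
    if area <= 0:
        raise ValueError("ROI area must be positive")
    return n * 20.0 / area


@dataclass(frozen=True)
class MonomerReference:
    """The single-protein calibration envelope.

    Purified monomeric protein imaged under the study protocol maps to
    micro-clusters of mean diameter 23 nm and mean 7 localizations; a free
    micro-cluster "matches the monomer reference" when both its diameter and
    its localization count fall within ``envelope_k`` reference SDs of those
    means.  (This envelope-membership fraction is this package's
    operationalisation of the published monomer-similarity comparison, whose
    exact computation is descriptive.)
    """

    mean_diameter_nm: float = 23.0
    mean_locs: float = 7.0
    sd_diameter_nm: float = 6.0
    sd_locs: float = 2.5
    envelope_k: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_diameter_nm <= 0 or self.mean_locs <= 0:
            raise ValueError("reference means must be positive")
        if not self.envelope_k > 0:
            raise ValueError("envelope_k must be positive")


def monomer_match_fraction(
    diameters_nm: Sequence[float],
    n_locs: Sequence[int],
    reference: MonomerReference,
) -> Optional[float]:
    """Fraction of micro-clusters inside the monomer reference envelope."""
    d = np.asarray(diameters_nm, dtype=float)
    n = np.asarray(n_locs, dtype=float)
    if d.size != n.size:
        raise ValueError("diameters and counts must have equal length")
    if d.size == 0:
        return None
    k = reference.envelope_k
    ok_d = np.abs(d - reference.mean_diameter_nm) <= k * reference.sd_diameter_nm
    ok_n = np.abs(n - reference.mean_locs) <= k * reference.sd_locs
    return float(np.mean(ok_d & ok_n))


# ---------------------------------------------------------------------------
# field summaries
# ---------------------------------------------------------------------------


def summarize_field(
    fc: FieldClusters,
    binning: SizeBinning,
    count_subsmall_as_free: bool = True,
) -> dict:
    """Per-field aggregate statistics feeding group comparisons."""
    counted = fc.counted_clusters(count_subsmall_as_free)
    hist = size_distribution(fc.clusters, binning)
    diameters = [c.mean_diameter_nm for c in counted]
    densities = [c.n_localizations for c in counted]
    md = fc.field.metadata
    pf = free_fraction(fc, count_subsmall_as_free)
    return {
        "subject": md.subject,
        "condition": md.condition,
        "imaging_day": md.imaging_day,
        "field_id": md.field_id,
        "n_localizations": len(fc.field),
        "n_clusters_retained": len(counted),
        "clusters_per_20um2": clusters_per_region(fc, count_subsmall_as_free=count_subsmall_as_free),
        "median_diameter_nm": float(np.median(diameters)) if diameters else math.nan,
        "mean_inner_density": float(np.mean(densities)) if densities else math.nan,
        "pct_free": math.nan if pf is None else pf,
        "n_sub_small": hist["sub_small"],
        "n_small": hist["small"],
        "n_medium": hist["medium"],
        "n_large": hist["large"],
        "n_very_large": hist["very_large"],
    }


def conservation_holds(fc: FieldClusters) -> bool:
    """Clustered + free localizations account for every localization once."""
    labels = fc.labeling.labels
    in_clusters = sum(c.member_indices.size for c in fc.clusters)
    n_noise = int(np.count_nonzero(labels == FREE))
    return in_clusters + n_noise == len(fc.field)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonDesign:
    """Which groups to compare, how, and on which metrics.

    ``comparisons`` lists the pairwise contrasts actually reported; the
    Bonferroni correction divides α by this count, not by all possible pairs.
    """

    metrics: Tuple[str, ...] = ("mean_inner_density", "pct_free")
    group_col: str = "condition"
    subject_col: str = "subject"
    comparisons: Optional[Tuple[Tuple[str, str], ...]] = None
    test: str = "welch"  # "welch" | "pooled"
    anova: Optional[str] = None  # None | "oneway" | "twoway"
    factors: Tuple[str, ...] = ()
    alpha: float = 0.05


def _per_subject_means(
    df: pd.DataFrame, metric: str, group_col: str, subject_col: str
) -> pd.DataFrame:
    return (
        df.groupby([group_col, subject_col], as_index=False)[metric]
        .mean()
        .dropna(subset=[metric])
    )


def ttest(
    a: Sequence[float], b: Sequence[float], kind: str = "welch"
) -> Tuple[float, float, float]:
    """Two-sample t test; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 biological replicates")
    if kind == "pooled":
        res = stats.ttest_ind(a, b, equal_var=True)
        dof = len(a) + len(b) - 2
    elif kind == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        dof = res.df if hasattr(res, "df") else np.nan
    else:
        raise ValueError("test must be 'welch' or 'pooled'")
    return float(res.statistic), float(dof), float(res.pvalue)


def one_way_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def two_way_anova(
    df: pd.DataFrame, value: str, factor_a: str, factor_b: str
) -> pd.DataFrame:
    """Balanced fixed-effects two-way ANOVA with interaction (type II SS)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    d = df.rename(columns={value: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = ols("_y ~ C(_fa) * C(_fb)", data=d).fit()
    return sm.stats.anova_lm(model, typ=2)


def group_compare(
    summaries: pd.DataFrame, design: ComparisonDesign
) -> dict:
    """Compare groups on per-subject means; Bonferroni-adjust pairwise p.

    Input is a field-summary table; fields are first averaged within each
    subject, which is the biological replicate.
    """
    report: dict = {"alpha": design.alpha, "metrics": {}}
    for metric in design.metrics:
        per_subj = _per_subject_means(
            summaries, metric, design.group_col, design.subject_col
        )
        groups = {
            g: sub[metric].to_numpy()
            for g, sub in per_subj.groupby(design.group_col)
        }
        for g, vals in groups.items():
            if len(vals) < 2:
                raise ValueError(
                    f"group {g!r} has fewer than 2 biological replicates for {metric}"
                )
        names = sorted(groups)
        comparisons = design.comparisons or tuple(itertools.combinations(names, 2))
        m = len(comparisons)
        pairwise = []
        for ga, gb in comparisons:
            t, dof, p = ttest(groups[ga], groups[gb], design.test)
            pairwise.append(
                {
                    "groups": [ga, gb],
                    "t": t,
                    "df": dof,
                    "p": p,
                    "p_bonferroni": min(1.0, p * m),
                    "significant": p * m < design.alpha,
                }
            )
        entry = {
            "groups": {
                g: {
                    "n": int(len(v)),
                    "mean": float(np.mean(v)),
                    "sem": float(stats.sem(v)) if len(v) > 1 else math.nan,
                }
                for g, v in groups.items()
            },
            "pairwise": pairwise,
        }
        if design.anova == "oneway" and len(names) > 2:
            f, p = one_way_anova([groups[g] for g in names])
            entry["anova"] = {"type": "oneway", "F": f, "p": p}
        elif design.anova == "twoway" and len(design.factors) == 2:
            tab = two_way_anova(summaries, metric, *design.factors)
            entry["anova"] = {
                "type": "twoway",
                "table": {
                    str(k): {"F": float(r["F"]), "p": float(r["PR(>F)"])}
                    for k, r in tab.iterrows()
                    if np.isfinite(r.get("F", np.nan))
                },
            }
        report["metrics"][metric] = entry
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of a group-comparison report."""
    lines = []
    for metric, entry in report["metrics"].items():
        lines.append(f"== {metric} ==")
        for g, s in entry["groups"].items():
            lines.append(f"  {g}: mean {s['mean']:.3f} ± {s['sem']:.3f} SEM (n={s['n']})")
        for pw in entry["pairwise"]:
            ga, gb = pw["groups"]
            star = " *" if pw["significant"] else ""
            lines.append(
                f"  {ga} vs {gb}: t={pw['t']:.3f}, df={pw['df']:.1f}, "
                f"p={pw['p']:.4f} (Bonferroni p={pw['p_bonferroni']:.4f}){star}"
            )
        if "anova" in entry:
            a = entry["anova"]
            if a["type"] == "oneway":
                lines.append(f"  one-way ANOVA: F={a['F']:.3f}, p={a['p']:.4f}")
            else:
                for term, r in a["table"].items():
                    lines.append(f"  two-way ANOVA {term}: F={r['F']:.3f}, p={r['p']:.4f}")
    return "\n".join(lines)
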