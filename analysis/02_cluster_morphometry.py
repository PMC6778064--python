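#!/usr/bin/env python
"""Step 2 — cluster the simulated fields and measure every aggregate.

Reads the CSV localization tables written by step 1, runs DBSCAN with the
default profile (eps 30 nm, min_pts 5), applies the per-imaging-day density
filter anchored on the placebo arm, and writes per-cluster morphometry plus
per-field summaries.

Usage: python analysis/02_cluster_morphometry.py [--fields results/fields]
                                                 [--out results]
"""

import argparse
from pathlib import Path

from clustorm.clustering import dbscan_cluster
from clustorm.compare import (
    DensityFilterPolicy,
    FieldClusters,
    apply_density_filter,
    summarize_field,
)
from clustorm.io import (
    FieldMetadata,
    Rect,
    read_localizations,
    summary_table,
    write_summary,
)
from clustorm.metrics import clusters_to_table, measure_clusters
from clustorm.scenarios import (
    DEFAULT_BINNING,
    DEFAULT_CLUSTERING,
    treatment_base_config,
)

import pandas as pd


def _metadata_from_name(stem: str) -> FieldMetadata:
    # names look like placebo_m0_f2_d2: condition_subject_field_day
    cond, mouse, fld, day = stem.split("_")
    return FieldMetadata(
        subject=f"{cond}_{mouse}", condition=cond, imaging_day=day,
        field_id=f"{cond}_{mouse}_{fld}",
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fields", default="results/fields")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cfg = treatment_base_config()
    roi = Rect(0, 0, cfg.roi_width_nm, cfg.roi_height_nm)
    records = []
    for path in sorted(Path(args.fields).glob("*.csv")):
        fld = read_localizations(path, roi=roi, metadata=_metadata_from_name(path.stem))
        lab = dbscan_cluster(fld, DEFAULT_CLUSTERING)
        clusters = measure_clusters(
            fld.xy, lab.labels, DEFAULT_BINNING, DEFAULT_CLUSTERING.outlier_sd
        )
        records.append(FieldClusters(fld, lab, clusters))

    thresholds = apply_density_filter(records, DensityFilterPolicy("placebo", 0.10))
    print("per-day exclusion thresholds (localizations/cluster):")
    for day, thr in sorted(thresholds.items()):
        print(f"  {day}: {thr:.2f}")

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    cluster_tables = []
    for rec in records:
        tab = clusters_to_table(rec.clusters)
        tab.insert(0, "field_id", rec.field.metadata.field_id)
        cluster_tables.append(tab)
    pd.concat(cluster_tables, ignore_index=True).to_csv(
        out / "clusters.tsv", sep="\t", index=False, float_format="%.3f"
    )

    summaries = summary_table([summarize_field(r, DEFAULT_BINNING) for r in records])
    write_summary(summaries, out / "field_summaries.tsv")
    print(f"\n{len(summaries)} fields summarized; "
          f"{sum(len(r.clusters) for r in records)} clusters measured")
    print(summaries.groupby("condition")[["pct_free", "mean_inner_density"]]
          .mean().round(2).to_string())


if __name__ == "__main__":
    main()
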