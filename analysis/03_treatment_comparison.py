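#!/usr/bin/env python
"""Step 3 — compare the placebo and treated arms.

Reads the per-field summaries from step 2, averages fields within each mouse
(the mouse is the biological replicate), runs Welch t tests with Bonferroni
correction on the headline metrics, and writes a statistics report.

Usage: python analysis/03_treatment_comparison.py [--summaries results/field_summaries.tsv]
                                                  [--out results/statistics.json]
"""

import argparse
import json
from pathlib import Path

from clustorm.compare import ComparisonDesign, format_report, group_compare
from clustorm.io import read_summary


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--summaries", default="results/field_summaries.tsv")
    ap.add_argument("--out", default="results/statistics.json")
    args = ap.parse_args()

    summaries = read_summary(args.summaries)
    design = ComparisonDesign(
        metrics=("pct_free", "mean_inner_density", "median_diameter_nm",
                 "clusters_per_20um2"),
        test="welch",
    )
    report = group_compare(summaries, design)

    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    print(format_report(report))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
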