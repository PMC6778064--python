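"""End-to-end orchestration: simulate → cluster → measure → filter →
summarize → compare, from one config, with reproducible seeding.

A single global seed fans out to per-stage / per-field seeds through
``numpy.random.SeedSequence(global_seed).spawn(...)``, so any stage can be
re-run in isolation with the identical stream.  Identical config + seed
produces byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .clustering import ClusteringParams, dbscan_cluster
from .compare import (
    ComparisonDesign,
    DensityFilterPolicy,
    FieldClusters,
    MonomerReference,
    apply_density_filter,
    conservation_holds,
    format_report,
    group_compare,
    summarize_field,
)
from .io import (
    read_localizations,
    summary_table,
    write_summary,
)
from .metrics import SizeBinning, clusters_to_table, measure_clusters
from .synthetic import LabeledField, SyntheticFieldConfig, generate_condition_pair

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Either ``manifest`` (a list of localization CSV records with subject /
    condition / imaging-day tags) or ``scenario`` (a synthetic two-arm
    design) must be provided.
    """

    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    binning: SizeBinning = field(default_factory=SizeBinning)
    policy: DensityFilterPolicy = field(default_factory=DensityFilterPolicy)
    monomer_reference: MonomerReference = field(default_factory=MonomerReference)
    comparison: ComparisonDesign = field(default_factory=ComparisonDesign)
    scenario: Optional[SyntheticFieldConfig] = None
    scenario_n_fields_per_arm: int = 6
    scenario_n_subjects_per_arm: int = 3
    manifest: Sequence[dict] = field(default_factory=list)
    apply_filter: bool = True
    count_subsmall_as_free: bool = True
    validate_conservation: bool = True
    out_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class PipelineResult:
    field_clusters: List[FieldClusters]
    summaries: pd.DataFrame
    report: dict
    thresholds: dict
    manifest: dict


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # surface the failing stage by name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("simulate")
def _load_fields(config: PipelineConfig) -> List[LabeledField]:
    if config.scenario is not None:
        return generate_condition_pair(
            config.scenario,
            n_fields_per_arm=config.scenario_n_fields_per_arm,
            seed=config.seed,
            n_subjects_per_arm=config.scenario_n_subjects_per_arm,
            reference_label=config.policy.reference_condition,
        )
    if not config.manifest:
        raise ValueError("config needs a scenario or a non-empty manifest")
    out = []
    for rec in config.manifest:
        fld = read_localizations(rec["path"], rec.get("dialect", "native"))
        fld = fld.with_metadata(
            subject=rec.get("subject", ""),
            condition=rec.get("condition", ""),
            imaging_day=rec.get("imaging_day", ""),
            field_id=rec.get("field_id", Path(rec["path"]).stem),
        )
        out.append(
            LabeledField(
                fld,
                None,
                fld.metadata.condition,
                fld.metadata.subject,
                fld.metadata.imaging_day,
                fld.metadata.field_id,
            )
        )
    return out


@_stage("cluster")
def _cluster_fields(
    fields: List[LabeledField], config: PipelineConfig
) -> List[FieldClusters]:
    out = []
    for lf in fields:
        labeling = dbscan_cluster(lf.field, config.clustering)
        clusters = measure_clusters(
            lf.field.xy, labeling.labels, config.binning, config.clustering.outlier_sd
        )
        out.append(FieldClusters(lf.field, labeling, clusters))
    return out


@_stage("density-filter")
def _filter(records: List[FieldClusters], config: PipelineConfig) -> dict:
    if not config.apply_filter:
        return {}
    return apply_density_filter(
        records, config.policy, config.count_subsmall_as_free
    )


@_stage("summarize")
def _summarize(records: List[FieldClusters], config: PipelineConfig) -> pd.DataFrame:
    rows = [
        summarize_field(fc, config.binning, config.count_subsmall_as_free)
        for fc in records
    ]
    return summary_table(rows)


@_stage("compare")
def _compare(summaries: pd.DataFrame, config: PipelineConfig) -> dict:
    return group_compare(summaries, config.comparison)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; optionally write a result bundle to out_dir."""
    logging.basicConfig(level=config.log_level)
    fields = _load_fields(config)
    records = _cluster_fields(fields, config)
    if config.validate_conservation:
        for fc in records:
            if not conservation_holds(fc):
                raise PipelineError(
                    f"stage 'cluster' failed: conservation violated in field "
                    f"{fc.field.metadata.field_id!r}"
                )
    thresholds = _filter(records, config)
    summaries = _summarize(records, config)
    report = _compare(summaries, config)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "clustering": asdict(config.clustering),
        "binning": {"boundaries_nm": list(config.binning.boundaries_nm)},
        "policy": asdict(config.policy),
        "thresholds": thresholds,
        "n_fields": len(records),
    }
    result = PipelineResult(records, summaries, report, thresholds, manifest)
    if config.out_dir:
        _write_bundle(result, config)
    return result


@_stage("write")
def _write_bundle(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_summary(result.summaries, out / "field_summaries.tsv")
    tables = []
    for fc in result.field_clusters:
        t = clusters_to_table(fc.clusters)
        t.insert(0, "field_id", fc.field.metadata.field_id)
        tables.append(t)
    if tables:
        pd.concat(tables, ignore_index=True).to_csv(
            out / "clusters.tsv", sep="\t", index=False, float_format="%.4f"
        )
    with open(out / "statistics.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
    with open(out / "statistics.txt", "w") as fh:
        fh.write(format_report(result.report) + "\n")
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# YAML config loading
# ---------------------------------------------------------------------------


def config_from_yaml(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (keys mirror the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "clustering" in raw:
        kwargs["clustering"] = ClusteringParams(**raw["clustering"])
    if "binning" in raw:
        kwargs["binning"] = SizeBinning(tuple(raw["binning"]["boundaries_nm"]))
    if "policy" in raw:
        kwargs["policy"] = DensityFilterPolicy(**raw["policy"])
    if "monomer_reference" in raw:
        kwargs["monomer_reference"] = MonomerReference(**raw["monomer_reference"])
    if "comparison" in raw:
        c = dict(raw["comparison"])
        if "metrics" in c:
            c["metrics"] = tuple(c["metrics"])
        if c.get("comparisons"):
            c["comparisons"] = tuple(tuple(p) for p in c["comparisons"])
        if "factors" in c:
            c["factors"] = tuple(c["factors"])
        kwargs["comparison"] = ComparisonDesign(**c)
    if "scenario" in raw:
        s = dict(raw["scenario"])
        from .laws import DistributionLaw

        for key in ("aggregate_diameter_law", "aggregate_density_law", "locs_per_monomer_law"):
            if s.get(key) is not None:
                s[key] = DistributionLaw.from_dict(s[key])
        if "effect_multipliers" in s:
            s["effect_multipliers"] = tuple(s["effect_multipliers"])
        kwargs["scenario"] = SyntheticFieldConfig(**s)
    for key in (
        "manifest",
        "apply_filter",
        "count_subsmall_as_free",
        "validate_conservation",
        "out_dir",
        "seed",
        "log_level",
        "scenario_n_fields_per_arm",
        "scenario_n_subjects_per_arm",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)
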