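"""Benchmark orchestration and environmental-dataset summaries.

`run_benchmark` reproduces the standard mock-community protocol: each
filter/parameter combination is run separately per dilution group — on that
group's biological samples plus all negative controls of the chosen role
(controls are dataset-level; they are not diluted) — scored per replicate
against the ground truth, and the scores averaged over replicates.

Per-replicate scoring evaluates the features actually observed in that
replicate's sample (nonzero count); a feature that never occurred in a
sample is not evidence for or against a classifier there.

For datasets without ground truth, `reduction_summary` reports the fraction
of reads and features kept by a filter, and `top_taxa_shift` the mean
relative abundance of the most abundant taxa before and after filtering
(after-abundances renormalised over the kept features).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ampdecon.filters import (
    FilterResult,
    frequency_result,
    presence_filter,
    ratio_filter,
    span_filter,
)
from ampdecon.metrics import ScoreSet, Weighting, confusion, scores
from ampdecon.tables import (
    FeatureTable,
    Role,
    SampleMetadata,
    TableError,
    relative_abundance,
)
from ampdecon.truth import TruthLabels

__all__ = ["BenchmarkSpec", "run_benchmark", "reduction_summary", "top_taxa_shift"]

SCORE_COLUMNS = [
    "sensitivity",
    "specificity",
    "accuracy",
    "baseline_accuracy",
    "precision",
    "mcc",
    "youden",
]


@dataclass
class BenchmarkSpec:
    """Grid of filters to benchmark and how to group/aggregate.

    ``grid`` maps a filter family to its parameter list: ``ratio`` and
    ``frequency`` take float thresholds, ``span`` integer counts,
    ``presence`` a single ``None``. ``group_key`` names the metadata column
    that defines the per-run groups (typically the dilution).
    """

    grid: list[tuple[str, list]]
    group_key: str = "group"
    control_role: Role | str = Role.NEG2
    weighting: Weighting | str = Weighting.FEATURE

    def __post_init__(self) -> None:
        if not self.grid:
            raise TableError("benchmark grid must be non-empty")
        known = {"presence", "ratio", "span", "frequency"}
        for family, params in self.grid:
            if family not in known:
                raise TableError(f"unknown filter family {family!r}; expected one of {sorted(known)}")
            if not params:
                raise TableError(f"empty parameter list for filter family {family!r}")


def _run_family(
    family: str,
    param,
    table: FeatureTable,
    meta: SampleMetadata,
    control_role: Role | str,
) -> FilterResult:
    if family == "presence":
        return presence_filter(table, meta, control_role)
    if family == "ratio":
        return ratio_filter(table, meta, control_role, float(param))
    if family == "span":
        return span_filter(table, meta, control_role, int(param))
    if family == "frequency":
        return frequency_result(table, meta, float(param))
    raise TableError(f"unknown filter family {family!r}")


def run_benchmark(
    table: FeatureTable,
    meta: SampleMetadata,
    truth: TruthLabels,
    spec: BenchmarkSpec,
) -> pd.DataFrame:
    """Score every (filter, parameter) on every group; mean over replicates.

    Returns one row per (filter, parameter, group) with the replicate count
    and replicate-averaged scores, sorted by filter, parameter and group.
    """
    if spec.group_key not in meta.frame.columns:
        raise TableError(f"metadata has no column {spec.group_key!r}")
    missing = [f for f in table.feature_ids if f not in set(truth.feature_ids)]
    if missing:
        raise TableError(f"truth labels lack feature {missing[0]!r}")

    bio = [s for s in meta.biological_samples() if s in set(table.sample_ids)]
    controls = [s for s in meta.controls(spec.control_role) if s in set(table.sample_ids)]
    if not controls:
        raise TableError(f"no controls of role {spec.control_role} in the table")
    groups_of = dict(zip(meta.frame["sample_id"], meta.frame[spec.group_key]))
    group_values: list[str] = []
    for s in bio:
        g = groups_of.get(s)
        if g is None or (isinstance(g, float) and math.isnan(g)):
            raise TableError(f"biological sample {s!r} has no {spec.group_key!r} value")
        if g not in group_values:
            group_values.append(str(g))

    rows = []
    for family, params in spec.grid:
        for param in params:
            for g in group_values:
                members = [s for s in bio if str(groups_of[s]) == g]
                if not members:
                    raise TableError(f"empty group {g!r}")
                sub = table.subset_samples(members + controls)
                result = _run_family(family, param, sub, meta, spec.control_role)
                per_rep: list[ScoreSet] = []
                for s in members:
                    col = sub.counts[:, sub.sample_index(s)]
                    observed = [f for f, c in zip(sub.feature_ids, col) if c > 0]
                    if not observed:
                        continue
                    c = confusion(
                        result,
                        truth,
                        sub,
                        weighting=spec.weighting,
                        sample_scope=[s],
                        feature_scope=observed,
                    )
                    per_rep.append(scores(c))
                row = {
                    "filter": family,
                    "parameter": param,
                    "group": g,
                    "n_replicates": len(per_rep),
                }
                for col_name in SCORE_COLUMNS:
                    vals = np.array([getattr(s, col_name) for s in per_rep], dtype=float)
                    row[col_name] = float(np.nanmean(vals)) if len(vals) and not np.all(np.isnan(vals)) else math.nan
                rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["filter", "parameter", "group"], kind="stable").reset_index(drop=True)


def reduction_summary(before: FeatureTable, after: FeatureTable) -> dict:
    """Reads and features kept by a filtering step, absolute and fractional."""
    missing = set(after.feature_ids) - set(before.feature_ids)
    if missing:
        raise TableError(f"after-table has features absent from before-table: {sorted(missing)[:3]}")
    reads_before = before.total_reads()
    reads_after = after.total_reads()
    return {
        "reads_before": reads_before,
        "reads_after": reads_after,
        "reads_kept_fraction": reads_after / reads_before if reads_before else 1.0,
        "features_before": before.n_features,
        "features_after": after.n_features,
        "features_kept_fraction": after.n_features / before.n_features if before.n_features else 1.0,
    }


def top_taxa_shift(
    before: FeatureTable,
    after: FeatureTable,
    meta: SampleMetadata,
    n: int = 10,
) -> pd.DataFrame:
    """Mean relative abundance of the top-``n`` taxa before vs after filtering.

    Taxa are the feature tables' taxonomy strings. "Before" ranks taxa by
    their mean relative abundance over biological samples in the unfiltered
    table; "after" shows the same taxa in the filtered table, renormalised
    over the kept features, so removing a major contaminant pushes the
    remaining taxa's after-abundances up.
    """
    if before.taxonomy is None:
        raise TableError("top_taxa_shift requires taxonomy annotations")
    if n < 1:
        raise TableError("n must be >= 1")
    missing = set(after.feature_ids) - set(before.feature_ids)
    if missing:
        raise TableError(f"after-table has features absent from before-table: {sorted(missing)[:3]}")

    bio = [s for s in meta.biological_samples() if s in set(before.sample_ids)]
    if not bio:
        raise TableError("no biological samples to summarise")

    def taxon_means(table: FeatureTable) -> pd.Series:
        view = relative_abundance(table.subset_samples([s for s in bio if s in set(table.sample_ids)]))
        per_sample = pd.DataFrame(view.values, index=table.feature_ids, columns=view.sample_ids)
        per_sample["taxon"] = table.taxonomy
        return per_sample.groupby("taxon").sum().mean(axis=1)

    before_means = taxon_means(before)
    after_means = taxon_means(after) if after.n_features else pd.Series(dtype=float)
    top = before_means.sort_values(ascending=False).head(n)
    return pd.DataFrame(
        {
            "taxon": top.index,
            "abundance_before": top.to_numpy(),
            "abundance_after": [float(after_means.get(t, 0.0)) for t in top.index],
        }
    ).reset_index(drop=True)
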