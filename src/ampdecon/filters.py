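"""Negative-control-based contaminant classifiers.

Three control-based filters operate on a feature table plus sample roles:

- **presence filter** — remove every feature seen (count > 0) in any
  negative control of the chosen type, regardless of abundance;
- **ratio filter** — remove a feature when the ratio of its mean relative
  abundance over the controls to its mean relative abundance over the
  biological samples exceeds a threshold (strictly). A systematic reagent
  contaminant should dominate the expectably empty controls, so its ratio
  is high; a genuine community member cross-contaminating a control has a
  low ratio. Means are plain means over *all* samples of the relevant role,
  zeros included.
- **span filter** — remove a feature present in at least ``k`` of the
  controls of the chosen type. Systematic contaminants recur across
  controls; sporadic cross-contamination from samples typically hits a
  single control, so ``k >= 2`` spares it. With ``k = 1`` the span filter
  is exactly the presence filter.

A sample-based **frequency filter** baseline is also provided in classifier
form (:func:`frequency_result`) so it can enter the same benchmarks: it
removes features that never reach a relative-abundance threshold in any
biological sample.

Edge conventions (each pinned by tests): the ratio is +inf when the sample
mean is 0 and the control mean positive (removed at any finite threshold);
a feature absent from both is recorded as NaN and kept (no evidence).
Removal is always global — the feature row is dropped everywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ampdecon.tables import (
    FeatureTable,
    Role,
    SampleMetadata,
    TableError,
    drop_features,
    relative_abundance,
)

__all__ = [
    "Decision",
    "CombineMode",
    "FilterResult",
    "presence_filter",
    "ratio_filter",
    "span_filter",
    "frequency_result",
    "combine_results",
    "external_decisions",
    "write_decisions",
    "apply_result",
]


class Decision(str, enum.Enum):
    REMOVE = "REMOVE"
    KEEP = "KEEP"


class CombineMode(str, enum.Enum):
    UNION = "UNION"
    INTERSECTION = "INTERSECTION"


@dataclass
class FilterResult:
    """Per-feature keep/remove decisions with the statistics behind them.

    ``frame`` is indexed by feature ID with columns ``mean_control_abundance``,
    ``mean_sample_abundance``, ``ratio`` (may be +inf or NaN), ``span_count``
    and ``decision``.
    """

    filter_name: str
    control_role: Role | None
    threshold: float | int | None
    frame: pd.DataFrame
    provenance: tuple["FilterResult", ...] = ()

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def removed(self) -> set[str]:
        return set(self.frame.index[self.frame["decision"] == Decision.REMOVE.value])

    @property
    def kept(self) -> set[str]:
        return set(self.frame.index[self.frame["decision"] == Decision.KEEP.value])

    def decision_of(self, feature_id: str) -> Decision:
        return Decision(self.frame.loc[feature_id, "decision"])


def _result_frame(
    table: FeatureTable,
    mean_control: np.ndarray,
    mean_sample: np.ndarray,
    ratio: np.ndarray,
    span: np.ndarray,
    remove: np.ndarray,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mean_control_abundance": mean_control,
            "mean_sample_abundance": mean_sample,
            "ratio": ratio,
            "span_count": span.astype(int),
            "decision": np.where(remove, Decision.REMOVE.value, Decision.KEEP.value),
        },
        index=pd.Index(table.feature_ids, name="feature_id"),
    )


def _control_stats(table: FeatureTable, meta: SampleMetadata, control_role: Role | str):
    role = Role.parse(control_role) if not isinstance(control_role, Role) else control_role
    controls = [s for s in meta.controls(role) if s in set(table.sample_ids)]
    samples = [s for s in meta.biological_samples() if s in set(table.sample_ids)]
    if not controls:
        raise TableError(f"no {role.value} controls present in the table")
    view = relative_abundance(table)
    cidx = [table.sample_index(s) for s in controls]
    sidx = [table.sample_index(s) for s in samples]
    mean_control = view.values[:, cidx].mean(axis=1) if cidx else np.zeros(table.n_features)
    mean_sample = view.values[:, sidx].mean(axis=1) if sidx else np.zeros(table.n_features)
    span = (table.counts[:, cidx] > 0).sum(axis=1)
    return role, controls, samples, mean_control, mean_sample, span


def presence_filter(
    table: FeatureTable, meta: SampleMetadata, control_role: Role | str
) -> FilterResult:
    """Remove every feature that appears in any control of the given role."""
    role, controls, _, mean_control, mean_sample, span = _control_stats(table, meta, control_role)
    remove = span >= 1
    ratio = _ratio_values(mean_control, mean_sample)
    return FilterResult(
        filter_name="presence",
        control_role=role,
        threshold=None,
        frame=_result_frame(table, mean_control, mean_sample, ratio, span, remove),
    )


def _ratio_values(mean_control: np.ndarray, mean_sample: np.ndarray) -> np.ndarray:
    ratio = np.full(mean_control.shape, np.nan)
    pos = mean_sample > 0
    ratio[pos] = mean_control[pos] / mean_sample[pos]
    ratio[(~pos) & (mean_control > 0)] = np.inf
    # both means zero -> NaN (feature absent from the run; no evidence)
    return ratio


def ratio_filter(
    table: FeatureTable,
    meta: SampleMetadata,
    control_role: Role | str,
    threshold: float,
) -> FilterResult:
    """Remove features whose control/sample mean-abundance ratio exceeds ``threshold``.

    The comparison is strict (``ratio > threshold``). Requires at least one
    control of the requested role and at least one biological sample.
    """
    if threshold < 0:
        raise TableError("ratio threshold must be >= 0")
    role, controls, samples, mean_control, mean_sample, span = _control_stats(
        table, meta, control_role
    )
    if not samples:
        raise TableError("ratio filter requires at least one biological sample")
    ratio = _ratio_values(mean_control, mean_sample)
    with np.errstate(invalid="ignore"):
        remove = ratio > threshold  # NaN compares False -> KEEP
    return FilterResult(
        filter_name="ratio",
        control_role=role,
        threshold=float(threshold),
        frame=_result_frame(table, mean_control, mean_sample, ratio, span, remove),
    )


def span_filter(
    table: FeatureTable,
    meta: SampleMetadata,
    control_role: Role | str,
    k: int,
) -> FilterResult:
    """Remove features present in at least ``k`` controls of the given role.

    ``k`` is an integer count out of the available controls ("k of n");
    ``1 <= k <= number of controls``. ``k=1`` reproduces the presence filter.
    """
    role, controls, _, mean_control, mean_sample, span = _control_stats(table, meta, control_role)
    if not (1 <= k <= len(controls)):
        raise TableError(f"span threshold k={k} out of range 1..{len(controls)}")
    remove = span >= k
    ratio = _ratio_values(mean_control, mean_sample)
    return FilterResult(
        filter_name="span",
        control_role=role,
        threshold=int(k),
        frame=_result_frame(table, mean_control, mean_sample, ratio, span, remove),
    )


def frequency_result(
    table: FeatureTable, meta: SampleMetadata, threshold: float
) -> FilterResult:
    """Sample-based frequency filter in classifier form.

    Removes a feature iff its relative abundance never reaches ``threshold``
    in any *biological* sample (controls are ignored). This is the baseline
    sample-based decontamination approach benchmarked against the
    control-based filters.
    """
    if not (0.0 <= threshold <= 1.0):
        raise TableError("frequency threshold must be in [0, 1]")
    samples = [s for s in meta.biological_samples() if s in set(table.sample_ids)]
    if not samples:
        raise TableError("frequency filter requires at least one biological sample")
    view = relative_abundance(table)
    sidx = [table.sample_index(s) for s in samples]
    maxima = view.values[:, sidx].max(axis=1)
    remove = maxima < threshold
    zeros = np.zeros(table.n_features)
    frame = _result_frame(table, zeros, view.values[:, sidx].mean(axis=1), np.full(table.n_features, np.nan), zeros, remove)
    frame["max_sample_abundance"] = maxima
    return FilterResult(
        filter_name="frequency",
        control_role=None,
        threshold=float(threshold),
        frame=frame,
    )


def combine_results(a: FilterResult, b: FilterResult, mode: CombineMode | str) -> FilterResult:
    """Combine two decision sets over the same features by union or intersection.

    UNION removes features removed by either parent; INTERSECTION those
    removed by both. Parent results are kept as provenance.
    """
    mode = CombineMode(str(mode).upper()) if not isinstance(mode, CombineMode) else mode
    if set(a.feature_ids) != set(b.feature_ids):
        raise TableError("combine_results requires identical feature sets")
    if mode == CombineMode.UNION:
        removed = a.removed | b.removed
    else:
        removed = a.removed & b.removed
    frame = a.frame.copy()
    frame["decision"] = [
        Decision.REMOVE.value if f in removed else Decision.KEEP.value for f in frame.index
    ]
    return FilterResult(
        filter_name=f"{a.filter_name}+{b.filter_name}({mode.value.lower()})",
        control_role=a.control_role,
        threshold=None,
        frame=frame,
        provenance=(a, b),
    )


def external_decisions(
    path: str | Path,
    table: FeatureTable | None = None,
    filter_name: str | None = None,
) -> FilterResult:
    """Load keep/remove decisions produced by an external tool.

    Expects a TSV with columns ``feature_id`` and ``decision`` (REMOVE/KEEP,
    case-insensitive) and optional ``score``. If a table is given, the file
    must cover exactly its features; unknown or missing IDs are an error.
    This is how decisions from external decontamination tools enter the
    benchmark without re-implementing them.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if "feature_id" not in df.columns or "decision" not in df.columns:
        raise TableError(f"{path}: expected columns feature_id and decision")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise TableError(f"{path}: duplicate feature ID {dup!r}")
    decisions = {}
    for fid, d in zip(df["feature_id"], df["decision"]):
        token = str(d).strip().upper()
        if token not in (Decision.REMOVE.value, Decision.KEEP.value):
            raise TableError(f"{path}: unknown decision {d!r} for feature {fid!r}")
        decisions[str(fid)] = token
    if table is not None:
        missing = [f for f in table.feature_ids if f not in decisions]
        if missing:
            raise TableError(f"{path}: no decision for feature {missing[0]!r}")
        unknown = [f for f in decisions if f not in set(table.feature_ids)]
        if unknown:
            raise TableError(f"{path}: unknown feature ID {unknown[0]!r}")
        order = table.feature_ids
    else:
        order = list(decisions)
    n = len(order)
    frame = pd.DataFrame(
        {
            "mean_control_abundance": np.nan,
            "mean_sample_abundance": np.nan,
            "ratio": np.nan,
            "span_count": 0,
            "decision": [decisions[f] for f in order],
        },
        index=pd.Index(order, name="feature_id"),
    )
    if "score" in df.columns:
        scores = dict(zip(df["feature_id"], pd.to_numeric(df["score"], errors="coerce")))
        frame["score"] = [scores.get(f, np.nan) for f in order]
    name = filter_name or "external"
    return FilterResult(filter_name=name, control_role=None, threshold=None, frame=frame)


def write_decisions(result: FilterResult, path: str | Path) -> None:
    """Write a decision TSV readable by :func:`external_decisions`."""
    out = pd.DataFrame(
        {
            "feature_id": result.feature_ids,
            "decision": [result.frame.loc[f, "decision"] for f in result.feature_ids],
        }
    )
    if "ratio" in result.frame.columns:
        out["score"] = result.frame["ratio"].to_numpy()
    out.to_csv(Path(path), sep="\t", index=False)


def apply_result(table: FeatureTable, result: FilterResult) -> FeatureTable:
    """Drop the features a result marks REMOVE; rows go from every sample."""
    missing = [f for f in table.feature_ids if f not in set(result.feature_ids)]
    if missing:
        raise TableError(f"filter result has no decision for feature {missing[0]!r}")
    return drop_features(table, result.removed & set(table.feature_ids))
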