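"""Evaluation of contaminant classifiers against ground truth.

The positive class is CONTAMINANT and the positive prediction is REMOVE:
a true positive is a removed contaminant, a false positive a removed mock
feature. From the confusion counts six scores are derived:

- sensitivity (recall) = TP / (TP + FN): correctly removed contaminants;
- specificity = TN / (TN + FP): correctly kept mock features;
- accuracy = (TP + TN) / total, to be read against the
- baseline accuracy = (TP + FN) / total, the contaminant prevalence — the
  accuracy of removing everything, and the score a trivial constant
  classifier attains under class imbalance;
- precision = TP / (TP + FP);
- MCC, the Matthews correlation between truth and prediction;
- Youden's index (bookmaker informedness) = sensitivity + specificity - 1,
  the class-imbalance-free summary: 1 is perfect, 0 as good as random,
  negative means reversed labels.

Counts can be feature-level (each ASV counts once) or read-weighted (each
feature weighted by its total reads within a chosen sample scope).
Undefined scores (e.g. precision when nothing was removed, sensitivity when
no contaminant exists) are carried as NaN, never silently as 0 — except
MCC, which by the usual convention is 0 when its denominator vanishes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ampdecon.filters import FilterResult
from ampdecon.tables import FeatureTable, TableError
from ampdecon.truth import CONTAMINANT, MOCK, TruthLabels

__all__ = ["Weighting", "ScoreSet", "confusion", "scores", "pr_grid"]


class Weighting(str, enum.Enum):
    FEATURE = "FEATURE"
    READ = "READ"


@dataclass
class ScoreSet:
    """Confusion counts plus derived scores under a stated weighting."""

    tp: float
    fp: float
    tn: float
    fn: float
    weighting: Weighting = Weighting.FEATURE
    sensitivity: float = math.nan
    specificity: float = math.nan
    accuracy: float = math.nan
    baseline_accuracy: float = math.nan
    precision: float = math.nan
    mcc: float = math.nan
    youden: float = math.nan

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "weighting": self.weighting.value,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "baseline_accuracy": self.baseline_accuracy,
            "precision": self.precision,
            "mcc": self.mcc,
            "youden": self.youden,
        }


def confusion(
    result: FilterResult,
    truth: TruthLabels,
    table: FeatureTable,
    weighting: Weighting | str = Weighting.FEATURE,
    sample_scope: Sequence[str] | None = None,
    feature_scope: Iterable[str] | None = None,
) -> ScoreSet:
    """Confusion counts of a filter's decisions against the truth labels.

    FEATURE weighting counts each feature once; READ weighting weights each
    feature by its total count over ``sample_scope`` (default: all samples
    of the table). ``feature_scope`` restricts the evaluation to a subset
    of features (e.g. those observed in one replicate).
    """
    weighting = Weighting(str(weighting).upper()) if not isinstance(weighting, Weighting) else weighting
    features = list(table.feature_ids) if feature_scope is None else [str(f) for f in feature_scope]
    missing = [f for f in features if f not in set(result.feature_ids)]
    if missing:
        raise TableError(f"filter result lacks a decision for feature {missing[0]!r}")
    missing = [f for f in features if f not in set(truth.feature_ids)]
    if missing:
        raise TableError(f"truth labels lack feature {missing[0]!r}")

    if weighting == Weighting.READ:
        scope = list(table.sample_ids) if sample_scope is None else list(sample_scope)
        sidx = [table.sample_index(s) for s in scope]
        totals = {
            f: float(table.counts[table.feature_index(f), sidx].sum()) for f in features
        }
        weight = totals.__getitem__
    else:
        weight = lambda f: 1.0  # noqa: E731

    removed = result.removed
    contaminants = truth.contaminant_ids
    tp = fp = tn = fn = 0.0
    for f in features:
        w = weight(f)
        is_contam = f in contaminants
        is_removed = f in removed
        if is_contam and is_removed:
            tp += w
        elif is_contam:
            fn += w
        elif is_removed:
            fp += w
        else:
            tn += w
    return ScoreSet(tp=tp, fp=fp, tn=tn, fn=fn, weighting=weighting)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def scores(counts: ScoreSet) -> ScoreSet:
    """Fill in the six evaluation scores from the confusion counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if min(tp, fp, tn, fn) < 0:
        raise TableError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    acc = _safe_div(tp + tn, total)
    base = _safe_div(tp + fn, total)
    prec = _safe_div(tp, tp + fp)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else 0.0
    youden = sens + spec - 1.0 if not (math.isnan(sens) or math.isnan(spec)) else math.nan
    return ScoreSet(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        weighting=counts.weighting,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        baseline_accuracy=base,
        precision=prec,
        mcc=mcc,
        youden=youden,
    )


def pr_grid(
    results: Sequence[FilterResult],
    truth: TruthLabels,
    table: FeatureTable,
    weighting: Weighting | str = Weighting.FEATURE,
    sample_scope: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Precision and sensitivity over a threshold grid of one filter family.

    All results must come from the same filter family; rows are ordered by
    threshold. Rows with undefined precision (nothing removed) are flagged
    in ``precision_defined``.
    """
    if not results:
        raise TableError("pr_grid needs at least one result")
    families = {r.filter_name for r in results}
    if len(families) != 1:
        raise TableError(f"pr_grid requires one filter family, got {sorted(families)}")
    rows = []
    for r in sorted(results, key=lambda r: (r.threshold is None, r.threshold)):
        s = scores(confusion(r, truth, table, weighting=weighting, sample_scope=sample_scope))
        rows.append(
            {
                "filter": r.filter_name,
                "threshold": r.threshold,
                "precision": s.precision,
                "sensitivity": s.sensitivity,
                "precision_defined": not math.isnan(s.precision),
            }
        )
    return pd.DataFrame(rows)
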