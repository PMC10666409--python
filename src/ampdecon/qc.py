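"""Pre-decontamination quality-control filters.

These steps precede control-based contaminant removal in a typical amplicon
workflow: dropping failed samples with too few reads, dropping features that
never exceed a minimal count (singletons/doubletons) or a minimal relative
abundance in any sample, and dropping features whose sequence length
deviates too far from the amplicon's expected length.

Boundary conventions (each asserted by tests):

- sample read-depth filter keeps a sample iff ``total > min_reads``
  (strict, matching the "> 5000 reads" style of depth cut-offs);
- the count and frequency feature filters keep a feature iff its maximum
  ``>= threshold`` ("reaching" the threshold keeps);
- the length filter removes a feature iff its relative deviation from the
  expected length is ``>= tolerance`` (deviation of exactly the tolerance
  is removed).

Filters compose in any order; relative abundances are recomputed from the
current table at each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ampdecon.tables import (
    FeatureTable,
    Role,
    SampleMetadata,
    TableError,
    drop_features,
    relative_abundance,
)

__all__ = [
    "QCOutcome",
    "filter_samples_min_reads",
    "filter_features_max_count",
    "filter_features_frequency",
    "filter_features_length",
]


@dataclass
class QCOutcome:
    """Accounting record of one QC step, plus the filtered table.

    ``reads_before - reads_after`` always equals the summed counts of the
    removed rows or columns.
    """

    step_name: str
    threshold: float
    removed_feature_ids: list[str] = field(default_factory=list)
    removed_sample_ids: list[str] = field(default_factory=list)
    reads_before: int = 0
    reads_after: int = 0
    features_before: int = 0
    features_after: int = 0
    samples_before: int = 0
    samples_after: int = 0
    table: FeatureTable | None = None
    metadata: SampleMetadata | None = None

    def summary_row(self) -> dict:
        return {
            "step": self.step_name,
            "threshold": self.threshold,
            "reads_before": self.reads_before,
            "reads_after": self.reads_after,
            "features_before": self.features_before,
            "features_after": self.features_after,
            "samples_before": self.samples_before,
            "samples_after": self.samples_after,
            "removed_features": len(self.removed_feature_ids),
            "removed_samples": len(self.removed_sample_ids),
        }


def _feature_outcome(step: str, threshold: float, table: FeatureTable, removed: list[str]) -> QCOutcome:
    after = drop_features(table, removed)
    return QCOutcome(
        step_name=step,
        threshold=threshold,
        removed_feature_ids=removed,
        reads_before=table.total_reads(),
        reads_after=after.total_reads(),
        features_before=table.n_features,
        features_after=after.n_features,
        samples_before=table.n_samples,
        samples_after=after.n_samples,
        table=after,
    )


def filter_samples_min_reads(
    table: FeatureTable,
    meta: SampleMetadata,
    min_reads: int,
    exempt_controls: bool = True,
) -> QCOutcome:
    """Drop biological samples with total reads <= ``min_reads``.

    Controls (NEG1/NEG2) are exempt by default: their low depth is expected
    and they are needed downstream. Pass ``exempt_controls=False`` to apply
    the cut to every sample.
    """
    if min_reads < 0:
        raise TableError("min_reads must be >= 0")
    totals = dict(zip(table.sample_ids, table.sample_totals()))
    removed: list[str] = []
    for s in table.sample_ids:
        role = meta.role_of(s)
        if exempt_controls and role != Role.SAMPLE:
            continue
        if totals[s] <= min_reads:
            removed.append(s)
    keep = [s for s in table.sample_ids if s not in set(removed)]
    after = table.subset_samples(keep)
    return QCOutcome(
        step_name="min_reads",
        threshold=min_reads,
        removed_sample_ids=removed,
        reads_before=table.total_reads(),
        reads_after=after.total_reads(),
        features_before=table.n_features,
        features_after=after.n_features,
        samples_before=table.n_samples,
        samples_after=after.n_samples,
        table=after,
        metadata=meta.subset(keep),
    )


def filter_features_max_count(table: FeatureTable, min_max_count: int) -> QCOutcome:
    """Drop features whose maximum count over all samples is below the cut.

    ``min_max_count=2`` removes singletons (features never seen more than
    once in any sample); kept iff ``max count >= min_max_count``.
    """
    if min_max_count < 0:
        raise TableError("min_max_count must be >= 0")
    if table.n_samples:
        maxima = table.counts.max(axis=1)
    else:
        maxima = np.zeros(table.n_features, dtype=np.int64)
    removed = [f for f, m in zip(table.feature_ids, maxima) if m < min_max_count]
    return _feature_outcome("max_count", min_max_count, table, removed)


def filter_features_frequency(table: FeatureTable, threshold: float) -> QCOutcome:
    """Drop features that never reach ``threshold`` relative abundance in any sample.

    Kept iff the feature's maximum per-sample relative abundance is
    ``>= threshold``. Removal is global: the whole feature row goes.
    """
    if not (0.0 <= threshold <= 1.0):
        raise TableError("frequency threshold must be in [0, 1]")
    view = relative_abundance(table)
    if table.n_samples:
        maxima = view.values.max(axis=1)
    else:
        maxima = np.zeros(table.n_features)
    removed = [f for f, m in zip(table.feature_ids, maxima) if m < threshold]
    return _feature_outcome("frequency", threshold, table, removed)


def filter_features_length(
    table: FeatureTable,
    expected_length: int,
    tolerance: float,
    sequences: Mapping[str, str] | None = None,
) -> QCOutcome:
    """Drop features whose sequence length deviates >= ``tolerance`` from expected.

    Deviation is ``|len - expected| / expected``; a feature at exactly the
    tolerance (e.g. 320 bp against 400 bp expected at tolerance 0.2) is
    removed. Sequences come from the table unless passed explicitly.
    """
    if expected_length <= 0:
        raise TableError("expected_length must be > 0")
    if not (0.0 <= tolerance < 1.0):
        raise TableError("length tolerance must be in [0, 1)")
    seqmap = dict(sequences) if sequences is not None else table.sequence_map()
    removed: list[str] = []
    for f in table.feature_ids:
        if f not in seqmap:
            raise TableError(f"feature {f!r} has no sequence for the length filter")
        dev = abs(len(seqmap[f]) - expected_length) / expected_length
        if dev >= tolerance:
            removed.append(f)
    return _feature_outcome("length", tolerance, table, removed)
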