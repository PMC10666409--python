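"""Feature-table, metadata and sequence I/O.

Conventions
-----------
Feature tables are TSV files with features as rows and samples as columns
(the usual ASV-table orientation). The first column holds the feature ID;
optional trailing columns named ``sequence`` and ``taxonomy`` are recognised
by name. Counts are integers and relative abundances are always derived,
never stored.

Sample metadata is a TSV with columns ``sample_id`` and ``role`` (one of
``sample``, ``NEG1``, ``NEG2``, case-insensitive) plus optional ``group``,
``replicate`` and ``dna_quant`` columns. By the convention of two-control
designs, NEG1 denotes PCR controls and NEG2 pipeline (extraction) controls,
but the roles are opaque labels to every operation here.

Sequences are nucleotide strings over A/C/G/T plus the IUPAC ambiguity
codes and N; ``U`` is normalised to ``T`` and case is folded to upper.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Role",
    "FeatureTable",
    "SampleMetadata",
    "RelAbundanceView",
    "TableError",
    "normalize_sequence",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_fasta",
    "write_fasta",
    "relative_abundance",
    "drop_features",
]

#: Valid nucleotide symbols after normalisation: the four bases plus the
#: eleven IUPAC ambiguity codes (N included).
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

RESERVED_COLUMNS = ("sequence", "taxonomy")


class TableError(ValueError):
    """Raised for malformed tables, metadata or sequence files."""


class Role(str, enum.Enum):
    """Role of a sample in the study design."""

    SAMPLE = "SAMPLE"
    NEG1 = "NEG1"
    NEG2 = "NEG2"

    @classmethod
    def parse(cls, token: "Role | str") -> "Role":
        if isinstance(token, cls):
            return token
        t = str(token).strip().upper()
        if t == "SAMPLE":
            return cls.SAMPLE
        if t in ("NEG1", "NEG2"):
            return cls(t)
        raise TableError(f"unknown role {token!r}: expected sample, NEG1 or NEG2")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string, map U->T, and validate the alphabet."""
    s = str(seq).strip().upper().replace("U", "T")
    bad = set(s) - IUPAC_ALPHABET
    if bad:
        raise TableError(f"invalid nucleotide symbol(s) {sorted(bad)} in sequence {seq[:30]!r}")
    return s


@dataclass
class FeatureTable:
    """Integer read counts for features (rows) by samples (columns).

    Parameters
    ----------
    feature_ids : ordered unique feature identifiers
    sample_ids : ordered unique sample identifiers
    counts : integer array of shape (n_features, n_samples), all >= 0
    sequences : optional per-feature nucleotide sequence (one per feature)
    taxonomy : optional per-feature annotation string
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    sequences: list[str] | None = None
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise TableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise TableError("counts must be finite integers")
        counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise TableError(
                f"negative count at feature {self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        self.counts = counts
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise TableError(f"duplicate {name} ID {x!r}")
                seen.add(x)
        if self.sequences is not None:
            if len(self.sequences) != len(self.feature_ids):
                raise TableError("sequences must have exactly one entry per feature")
            self.sequences = [normalize_sequence(s) for s in self.sequences]
        if self.taxonomy is not None and len(self.taxonomy) != len(self.feature_ids):
            raise TableError("taxonomy must have exactly one entry per feature")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise TableError(f"unknown feature ID {feature_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise TableError(f"unknown sample ID {sample_id!r}") from None

    def sample_totals(self) -> np.ndarray:
        """Total reads per sample, in sample order."""
        return self.counts.sum(axis=0)

    def total_reads(self) -> int:
        return int(self.counts.sum())

    def sequence_map(self) -> dict[str, str]:
        if self.sequences is None:
            raise TableError("feature table carries no sequences")
        return dict(zip(self.feature_ids, self.sequences))

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        """Return a table restricted to the given samples (order as given)."""
        idx = [self.sample_index(s) for s in sample_ids]
        return FeatureTable(
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            counts=self.counts[:, idx],
            sequences=None if self.sequences is None else list(self.sequences),
            taxonomy=None if self.taxonomy is None else list(self.taxonomy),
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        """Return a table restricted to the given features (order as given)."""
        idx = [self.feature_index(f) for f in feature_ids]
        return FeatureTable(
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :],
            sequences=None if self.sequences is None else [self.sequences[i] for i in idx],
            taxonomy=None if self.taxonomy is None else [self.taxonomy[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (features x samples), plus sequence/taxonomy columns."""
        df = pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)
        df.index.name = "feature_id"
        if self.sequences is not None:
            df["sequence"] = self.sequences
        if self.taxonomy is not None:
            df["taxonomy"] = self.taxonomy
        return df


@dataclass
class SampleMetadata:
    """Per-sample study-design annotations keyed by sample ID."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if "sample_id" not in df.columns or "role" not in df.columns:
            raise TableError("metadata requires 'sample_id' and 'role' columns")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise TableError(f"duplicate sample_id {dup!r} in metadata")
        df["role"] = [Role.parse(r) for r in df["role"]]
        for col in ("group", "replicate"):
            if col not in df.columns:
                df[col] = None
        if "dna_quant" not in df.columns:
            df["dna_quant"] = np.nan
        else:
            df["dna_quant"] = pd.to_numeric(df["dna_quant"], errors="coerce")
            if (df["dna_quant"].dropna() < 0).any():
                raise TableError("dna_quant must be non-negative")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def role_of(self, sample_id: str) -> Role:
        rows = self.frame[self.frame["sample_id"] == sample_id]
        if rows.empty:
            raise TableError(f"unknown sample ID {sample_id!r} in metadata")
        return rows["role"].iloc[0]

    def ids_with_role(self, role: Role | str) -> list[str]:
        role = Role.parse(role) if not isinstance(role, Role) else role
        return list(self.frame.loc[self.frame["role"] == role, "sample_id"])

    def biological_samples(self) -> list[str]:
        return self.ids_with_role(Role.SAMPLE)

    def controls(self, role: Role | str) -> list[str]:
        role = Role.parse(role) if not isinstance(role, Role) else role
        if role == Role.SAMPLE:
            raise TableError("controls() expects NEG1 or NEG2")
        return self.ids_with_role(role)

    def group_of(self, sample_id: str) -> str | None:
        rows = self.frame[self.frame["sample_id"] == sample_id]
        if rows.empty:
            raise TableError(f"unknown sample ID {sample_id!r} in metadata")
        g = rows["group"].iloc[0]
        return None if g is None or (isinstance(g, float) and np.isnan(g)) else str(g)

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        keep = set(sample_ids)
        return SampleMetadata(self.frame[self.frame["sample_id"].isin(keep)].copy())

    def cross_validate(self, table: FeatureTable) -> list[str]:
        """IDs present in metadata but absent from the table (orphans)."""
        return [s for s in self.sample_ids if s not in set(table.sample_ids)]


@dataclass
class RelAbundanceView:
    """Per-sample relative abundances with the same shape as a FeatureTable.

    Samples whose total read count is zero carry all-zero values and are
    listed in ``zero_total_samples`` rather than raising.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    zero_total_samples: list[str] = field(default_factory=list)

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


def relative_abundance(table: FeatureTable) -> RelAbundanceView:
    """Per-sample relative abundance: count / sample total.

    Zero-total samples are flagged and given all-zero columns; for every
    other sample the column sums to 1.
    """
    totals = table.sample_totals().astype(float)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    values = table.counts / safe[None, :]
    values[:, zero] = 0.0
    return RelAbundanceView(
        feature_ids=list(table.feature_ids),
        sample_ids=list(table.sample_ids),
        values=values,
        zero_total_samples=[s for s, z in zip(table.sample_ids, zero) if z],
    )


def drop_features(table: FeatureTable, feature_ids: Iterable[str]) -> FeatureTable:
    """Remove the given feature rows; samples and remaining counts unchanged."""
    to_drop = set(str(f) for f in feature_ids)
    unknown = to_drop - set(table.feature_ids)
    if unknown:
        raise TableError(f"unknown feature ID(s) {sorted(unknown)}")
    keep = [f for f in table.feature_ids if f not in to_drop]
    return table.subset_features(keep)


# ---------------------------------------------------------------------------
# TSV I/O


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a features-x-samples TSV count table.

    The first column is the feature ID; remaining columns are per-sample
    integer counts, except trailing columns named ``sequence``/``taxonomy``.
    Non-integer, negative or missing cells are a :class:`TableError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.ParserError as e:
        raise TableError(f"{path}: ragged or malformed TSV ({e})") from e
    if df.shape[1] < 2:
        raise TableError(f"{path}: expected a feature-ID column plus at least one sample column")
    id_col = df.columns[0]
    feature_ids = df[id_col].astype(str).tolist()
    dup = df[id_col][df[id_col].duplicated()]
    if not dup.empty:
        raise TableError(f"{path}: duplicate feature ID {dup.iloc[0]!r}")
    sequences = taxonomy = None
    data_cols = list(df.columns[1:])
    if "sequence" in data_cols:
        sequences = df["sequence"].astype(str).tolist()
        data_cols.remove("sequence")
    if "taxonomy" in data_cols:
        taxonomy = df["taxonomy"].astype(str).tolist()
        data_cols.remove("taxonomy")
    counts = np.empty((len(feature_ids), len(data_cols)), dtype=np.int64)
    for j, col in enumerate(data_cols):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            row = feature_ids[int(parsed.isna().idxmax())]
            raise TableError(f"{path}: non-numeric or missing count in column {col!r}, feature {row!r}")
        vals = parsed.to_numpy(dtype=float)
        if np.any(vals != np.floor(vals)):
            row = feature_ids[int(np.argmax(vals != np.floor(vals)))]
            raise TableError(f"{path}: non-integer count in column {col!r}, feature {row!r}")
        if np.any(vals < 0):
            row = feature_ids[int(np.argmax(vals < 0))]
            raise TableError(f"{path}: negative count in column {col!r}, feature {row!r}")
        counts[:, j] = vals.astype(np.int64)
    return FeatureTable(
        feature_ids=feature_ids,
        sample_ids=[str(c) for c in data_cols],
        counts=counts,
        sequences=sequences,
        taxonomy=taxonomy,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as TSV; inverse of :func:`read_feature_table`."""
    table.to_frame().to_csv(Path(path), sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample-metadata TSV (columns sample_id, role, ...)."""
    df = pd.read_csv(Path(path), sep="\t", header=0, dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.frame.copy()
    df["role"] = [r.value for r in df["role"]]
    df.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA I/O (Bio.SeqIO underneath; wrapped and unwrapped records both fine)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> normalised-sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise TableError(f"{path}: duplicate FASTA ID {rec.id!r}")
        out[rec.id] = normalize_sequence(str(rec.seq))
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(normalize_sequence(s)), id=str(i), description="")
        for i, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
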