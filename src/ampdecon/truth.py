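"""Mock-vs-contaminant ground truth by edit distance to reference sequences.

In a mock-community benchmark every feature (ASV) is either *mock* — it
matches one of the known reference sequences of the community, up to a few
nucleotides of sequencing/denoising error — or a *contaminant*. Matching is
Levenshtein edit distance, optionally tolerating IUPAC ambiguity codes
(a substitution is free when the two symbols' base sets intersect, e.g.
R matches A or G and N matches anything; insertions and deletions always
cost 1, ambiguity codes included).

Distances are computed with edlib on uppercase, U->T-normalised sequences.
Two labeling modes mirror common practice: a distance cut-off (typically
<= 4 bp to any reference) and a stricter exact-or-one-mismatch rule.
References may be full-length genes while queries are shorter amplicons;
``windowed=True`` switches to infix (semiglobal) alignment, scoring the
query against its best-matching stretch of the reference.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Mapping

import edlib
import pandas as pd

from ampdecon.tables import IUPAC_ALPHABET, TableError, normalize_sequence

__all__ = [
    "LabelMode",
    "TruthLabels",
    "edit_distance",
    "label_features",
    "IUPAC_SETS",
]

#: Base sets of the IUPAC nucleotide codes (after U->T normalisation).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# all unordered symbol pairs whose base sets intersect; passed to edlib so
# such substitutions cost 0
_IUPAC_EQUALITIES: list[tuple[str, str]] = [
    (x, y)
    for x, y in itertools.combinations(sorted(IUPAC_SETS), 2)
    if IUPAC_SETS[x] & IUPAC_SETS[y]
]


class LabelMode(str, enum.Enum):
    """How a feature qualifies as mock."""

    DISTANCE = "DISTANCE"  # min distance to any reference <= max_dist
    EXACT_OR_1NT = "EXACT_OR_1NT"  # distance <= 1


MOCK = "MOCK"
CONTAMINANT = "CONTAMINANT"


def edit_distance(
    a: str,
    b: str,
    iupac_tolerant: bool = False,
    infix: bool = False,
    max_dist: int | None = None,
) -> int:
    """Levenshtein distance between two nucleotide strings.

    Substitutions, insertions and deletions each cost 1. With
    ``iupac_tolerant`` a substitution between symbols whose IUPAC base sets
    intersect costs 0. With ``infix`` the distance is semiglobal: ``a`` is
    aligned against the best-matching stretch of ``b`` (gaps at b's ends
    are free), for matching short amplicons against gene-scale references.
    ``max_dist`` caps the search; -1 is returned when the distance exceeds it.
    """
    a = normalize_sequence(a)
    b = normalize_sequence(b)
    kwargs: dict = {"task": "distance", "mode": "HW" if infix else "NW"}
    if iupac_tolerant:
        kwargs["additionalEqualities"] = _IUPAC_EQUALITIES
    if max_dist is not None:
        kwargs["k"] = max_dist
    return int(edlib.align(a, b, **kwargs)["editDistance"])


@dataclass
class TruthLabels:
    """Per-feature ground truth: MOCK or CONTAMINANT.

    ``frame`` is indexed by feature ID with columns ``label``,
    ``best_reference_id`` (None for contaminants) and ``distance``
    (edit distance to the best reference; None for contaminants when the
    exact distance was not computed under the cap).
    """

    frame: pd.DataFrame

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.index)

    def label_of(self, feature_id: str) -> str:
        return str(self.frame.loc[feature_id, "label"])

    @property
    def mock_ids(self) -> set[str]:
        return set(self.frame.index[self.frame["label"] == MOCK])

    @property
    def contaminant_ids(self) -> set[str]:
        return set(self.frame.index[self.frame["label"] == CONTAMINANT])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TruthLabels":
        df = pd.read_csv(path, sep="\t", index_col="feature_id", dtype={"label": str})
        bad = set(df["label"]) - {MOCK, CONTAMINANT}
        if bad:
            raise TableError(f"unknown truth label(s) {sorted(bad)}")
        return cls(df)

    @classmethod
    def from_mapping(cls, labels: Mapping[str, str]) -> "TruthLabels":
        frame = pd.DataFrame(
            {
                "label": [labels[f] for f in labels],
                "best_reference_id": None,
                "distance": None,
            },
            index=pd.Index(list(labels), name="feature_id"),
        )
        bad = set(frame["label"]) - {MOCK, CONTAMINANT}
        if bad:
            raise TableError(f"unknown truth label(s) {sorted(bad)}")
        return cls(frame)


def label_features(
    sequences: Mapping[str, str],
    references: Mapping[str, str],
    max_dist: int = 4,
    mode: LabelMode | str = LabelMode.DISTANCE,
    iupac_tolerant: bool = False,
    windowed: bool = False,
) -> TruthLabels:
    """Label each feature MOCK or CONTAMINANT by distance to the references.

    DISTANCE mode: MOCK iff the minimum edit distance to any reference is
    ``<= max_dist``. EXACT_OR_1NT mode: MOCK iff the distance is ``<= 1``.
    Ties on distance go to the first reference in input order. Features
    beyond the cut are CONTAMINANT with no best reference recorded.
    """
    mode = LabelMode(str(mode).upper()) if not isinstance(mode, LabelMode) else mode
    if not references:
        raise TableError("label_features requires a non-empty reference set")
    cut = 1 if mode == LabelMode.EXACT_OR_1NT else int(max_dist)
    ref_items = [(rid, normalize_sequence(rs)) for rid, rs in references.items()]
    rows = []
    for fid, seq in sequences.items():
        if seq is None or seq == "":
            raise TableError(f"feature {fid!r} lacks a sequence")
        best_id, best_d = None, None
        for rid, rs in ref_items:
            d = edit_distance(seq, rs, iupac_tolerant=iupac_tolerant, infix=windowed, max_dist=cut)
            if d < 0:
                continue  # beyond the cap
            if best_d is None or d < best_d:
                best_id, best_d = rid, d
                if d == 0:
                    break
        if best_d is not None and best_d <= cut:
            rows.append((fid, MOCK, best_id, best_d))
        else:
            rows.append((fid, CONTAMINANT, None, None))
    frame = pd.DataFrame(
        rows, columns=["feature_id", "label", "best_reference_id", "distance"]
    ).set_index("feature_id")
    return TruthLabels(frame)
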