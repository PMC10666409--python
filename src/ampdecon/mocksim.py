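"""Seeded simulation of contaminated mock-community dilution series.

The generator emulates the structure of a decontamination benchmark:
a defined mixture of taxa ("mock community") serially diluted from high to
low bacterial input, sequenced alongside negative controls, with a shared
pool of reagent contaminants.

The contamination model is a constant absolute contaminant load: reagents
contribute a fixed effective input of ``contaminant_load_cells`` (λ) cells
to every sample regardless of how much real material went in, so at input
``N`` cells the expected contaminant read fraction is ``λ / (N + λ)`` —
negligible at high biomass and dominant below ~10^6 cells for the default
λ = 2×10^6. Contaminant identities and their relative weights are drawn
once per dataset (systematic contaminants recur across samples and
controls) from a heavy-tailed log-normal law.

Pipeline negative controls contain the contaminant pool, plus sporadic
cross-contamination: each mock taxon enters each pipeline control
independently with probability ``cross_contam_prob`` at a small relative
weight. PCR controls are near-empty (a fraction of a percent of the
samples' depth) and contain contaminants only.

Every feature carries a sequence: mock features are their taxon's
reference with at most 4 random edits, contaminants are random sequences
verified to lie at least 8 edits from every reference, so the distance-4
truth-labeling rule recovers the planted labels exactly. A single integer
seed makes the output bit-identical across runs.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ampdecon.tables import FeatureTable, SampleMetadata, TableError
from ampdecon.truth import CONTAMINANT, MOCK, TruthLabels, edit_distance

__all__ = ["Preset", "MockDesign", "preset_design", "simulate", "expected_contaminant_fraction"]


class Preset(str, enum.Enum):
    EVEN = "EVEN"
    STAGGERED_A = "STAGGERED_A"
    STAGGERED_B = "STAGGERED_B"


@dataclass
class MockDesign:
    """Full specification of one simulated benchmark dataset.

    ``taxa`` are (name, expected proportion) pairs summing to 1;
    ``dilution_cells`` the strictly decreasing series of bacterial input
    cells; λ = ``contaminant_load_cells`` the constant effective reagent
    input per sample. ``depth_mean`` is the biological samples' mean
    sequencing depth (reads); controls are scaled by
    ``control_depth_scale`` (pipeline) and ``pcr_depth_scale`` (PCR).
    """

    name: str
    taxa: list[tuple[str, float]]
    dilution_cells: list[float]
    replicates_per_dilution: int = 1
    n_pipeline_controls: int = 1
    n_pcr_controls: int = 0
    contaminant_pool_size: int = 50
    contaminant_load_cells: float = 2e6
    contaminant_weight_dispersion: float = 1.5
    cross_contam_prob: float = 0.0
    cross_contam_weight: float = 0.01
    depth_mean: float = 20000.0
    depth_dispersion: float = 0.3
    control_depth_scale: float = 0.1
    pcr_depth_scale: float = 0.005
    ref_length: int = 300
    mock_edit_max: int = 4
    contaminant_min_dist: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.taxa:
            raise TableError("design needs at least one mock taxon")
        props = np.array([p for _, p in self.taxa], dtype=float)
        if np.any(props <= 0) or np.any(props > 1):
            raise TableError("taxon proportions must lie in (0, 1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise TableError(f"taxon proportions sum to {props.sum():.12f}, expected 1")
        cells = np.array(self.dilution_cells, dtype=float)
        if cells.size == 0 or np.any(cells <= 0):
            raise TableError("dilution_cells must be positive")
        if np.any(np.diff(cells) >= 0):
            raise TableError("dilution_cells must be strictly decreasing")
        if self.replicates_per_dilution < 1:
            raise TableError("replicates_per_dilution must be >= 1")
        if self.contaminant_pool_size < 1:
            raise TableError("contaminant_pool_size must be >= 1")
        if self.contaminant_load_cells <= 0:
            raise TableError("contaminant_load_cells must be > 0")
        if self.depth_mean <= 0:
            raise TableError("depth_mean must be > 0")
        if not (0.0 <= self.cross_contam_prob <= 1.0):
            raise TableError("cross_contam_prob must be in [0, 1]")
        if self.ref_length < 20:
            raise TableError("ref_length must be >= 20")
        if self.contaminant_min_dist <= self.mock_edit_max:
            raise TableError("contaminant_min_dist must exceed mock_edit_max")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["taxa"] = [[n, p] for n, p in self.taxa]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MockDesign":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        payload["taxa"] = [(str(n), float(x)) for n, x in payload["taxa"]]
        return cls(**payload)


def expected_contaminant_fraction(design: MockDesign, cells: float) -> float:
    """Expected contaminant read fraction λ / (N + λ) at input ``cells``."""
    lam = design.contaminant_load_cells
    return lam / (cells + lam)


def _even_proportions() -> list[float]:
    # endpoints at 6% and 22%; six interior values linearly spaced and
    # positioned so the eight proportions sum exactly to 1
    interior = [0.06 + 0.16 * x for x in np.linspace(0.125, 0.625, 6)]
    return [0.06, *interior, 0.22]


def _staggered_a_proportions() -> list[float]:
    # geometric series over exactly two orders of magnitude (max/min = 100),
    # normalised to sum to 1
    raw = np.geomspace(1.0, 100.0, 15)
    return list(raw / raw.sum())


def preset_design(name: Preset | str, seed: int = 0) -> MockDesign:
    """Built-in study designs emulating three mock-community benchmarks.

    EVEN: 8 taxa of 6–22% expected abundance, threefold serial dilutions
    from 1.5e9 down to ~2.3e5 input cells, one pipeline control.
    STAGGERED_A: 15 taxa spanning two orders of magnitude in abundance,
    tenfold dilutions from 1e9 to 1e2 cells in triplicate, three pipeline
    and three PCR controls.
    STAGGERED_B: 3 taxa of 3–84.3% relative weight, two 20-fold dilutions
    (1.1e5 and 5.55e3 cells) in quadruplicate, four pipeline and two PCR
    controls, with substantial cross-contamination into the controls and a
    much lower reagent load.
    """
    preset = Preset(str(name).upper()) if not isinstance(name, Preset) else name
    if preset == Preset.EVEN:
        props = _even_proportions()
        return MockDesign(
            name="even",
            taxa=[(f"EvenTaxon{i+1:02d}", p) for i, p in enumerate(props)],
            dilution_cells=[1.5e9 / 3**k for k in range(9)],
            replicates_per_dilution=1,
            n_pipeline_controls=1,
            n_pcr_controls=0,
            contaminant_pool_size=60,
            contaminant_load_cells=2e6,
            cross_contam_prob=0.3,
            cross_contam_weight=0.01,
            depth_mean=50000.0,
            depth_dispersion=0.2,
            ref_length=253,
            seed=seed,
        )
    if preset == Preset.STAGGERED_A:
        props = _staggered_a_proportions()
        return MockDesign(
            name="staggered_a",
            taxa=[(f"StaggeredATaxon{i+1:02d}", p) for i, p in enumerate(props)],
            dilution_cells=[1e9 / 10**k for k in range(8)],
            replicates_per_dilution=3,
            n_pipeline_controls=3,
            n_pcr_controls=3,
            contaminant_pool_size=50,
            contaminant_load_cells=2e6,
            cross_contam_prob=0.02,
            cross_contam_weight=0.01,
            depth_mean=14000.0,
            depth_dispersion=0.3,
            ref_length=362,
            seed=seed,
        )
    if preset == Preset.STAGGERED_B:
        return MockDesign(
            name="staggered_b",
            taxa=[("SpikeTaxonHigh", 0.843), ("SpikeTaxonMid", 0.127), ("SpikeTaxonLow", 0.03)],
            dilution_cells=[1.1e5, 5.55e3],
            replicates_per_dilution=4,
            n_pipeline_controls=4,
            n_pcr_controls=2,
            contaminant_pool_size=30,
            contaminant_load_cells=3e3,
            cross_contam_prob=0.5,
            cross_contam_weight=0.02,
            depth_mean=25000.0,
            depth_dispersion=0.3,
            ref_length=362,
            seed=seed,
        )
    raise TableError(f"unknown preset {name!r}")


_BASES = np.array(list("ACGT"))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _apply_edits(rng: np.random.Generator, seq: str, n_edits: int) -> str:
    """Apply ``n_edits`` random substitutions/insertions/deletions."""
    s = list(seq)
    for _ in range(n_edits):
        op = rng.integers(0, 3)
        if op == 0 or len(s) <= 20:  # substitution
            i = int(rng.integers(0, len(s)))
            choices = [b for b in "ACGT" if b != s[i]]
            s[i] = choices[int(rng.integers(0, 3))]
        elif op == 1:  # insertion
            i = int(rng.integers(0, len(s) + 1))
            s.insert(i, str(rng.choice(_BASES)))
        else:  # deletion
            i = int(rng.integers(0, len(s)))
            del s[i]
    return "".join(s)


def simulate(
    design: MockDesign,
) -> tuple[FeatureTable, SampleMetadata, TruthLabels, dict[str, str]]:
    """Generate one dataset: counts, metadata, planted truth and references.

    Returns the feature table (mock features first, then contaminants),
    sample metadata (biological samples with ``group`` set to the input
    cell count, pipeline controls as NEG2, PCR controls as NEG1), the
    planted truth labels, and the mock reference sequences keyed by
    reference ID. Identical designs (same seed) yield identical output.
    """
    master = np.random.SeedSequence(design.seed)
    n_taxa = len(design.taxa)
    n_pool = design.contaminant_pool_size
    n_bio = len(design.dilution_cells) * design.replicates_per_dilution
    n_ctrl = design.n_pipeline_controls + design.n_pcr_controls
    children = master.spawn(2 + n_bio + n_ctrl)
    rng_seq = np.random.default_rng(children[0])
    rng_pool = np.random.default_rng(children[1])
    sample_rngs = [np.random.default_rng(c) for c in children[2:]]

    # --- sequences and planted truth -------------------------------------
    references: dict[str, str] = {}
    mock_seqs: list[str] = []
    for i, (taxon, _) in enumerate(design.taxa):
        ref = _random_sequence(rng_seq, design.ref_length)
        references[f"REF_{taxon}"] = ref
        mock_seqs.append(_apply_edits(rng_seq, ref, int(rng_seq.integers(0, design.mock_edit_max + 1))))
    contam_seqs: list[str] = []
    ref_list = list(references.values())
    while len(contam_seqs) < n_pool:
        cand = _random_sequence(rng_seq, design.ref_length)
        near = any(
            edit_distance(cand, r, max_dist=design.contaminant_min_dist - 1) >= 0
            for r in ref_list
        )
        if not near:
            contam_seqs.append(cand)

    feature_ids = [f"ASV_{i+1:04d}" for i in range(n_taxa + n_pool)]
    taxonomy = [t for t, _ in design.taxa] + [f"ContamGenus{j+1:02d}" for j in range(n_pool)]
    sequences = mock_seqs + contam_seqs

    truth_rows = []
    ref_ids = list(references)
    for i in range(n_taxa):
        d = min(edit_distance(mock_seqs[i], r) for r in ref_list)
        truth_rows.append((feature_ids[i], MOCK, ref_ids[i], d))
    for j in range(n_pool):
        truth_rows.append((feature_ids[n_taxa + j], CONTAMINANT, None, None))
    truth = TruthLabels(
        pd.DataFrame(truth_rows, columns=["feature_id", "label", "best_reference_id", "distance"])
        .set_index("feature_id")
    )

    # --- systematic contaminant weights (one draw per dataset) -----------
    weights = rng_pool.lognormal(mean=0.0, sigma=design.contaminant_weight_dispersion, size=n_pool)
    weights /= weights.sum()
    mock_props = np.array([p for _, p in design.taxa], dtype=float)
    lam = design.contaminant_load_cells

    # --- samples ----------------------------------------------------------
    n_features = n_taxa + n_pool
    columns: list[np.ndarray] = []
    meta_rows: list[dict] = []
    k = 0
    for di, cells in enumerate(design.dilution_cells):
        contam_frac = lam / (cells + lam)
        probs = np.concatenate([mock_props * (1 - contam_frac), weights * contam_frac])
        for rep in range(design.replicates_per_dilution):
            rng = sample_rngs[k]
            depth = max(1, int(round(rng.lognormal(math.log(design.depth_mean), design.depth_dispersion))))
            columns.append(rng.multinomial(depth, probs))
            sid = f"D{di+1:02d}R{rep+1}"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "role": "SAMPLE",
                    "group": f"{cells:.6g}",
                    "replicate": str(rep + 1),
                    "dna_quant": cells,
                }
            )
            k += 1
    for c in range(design.n_pipeline_controls):
        rng = sample_rngs[k]
        depth = max(
            1,
            int(round(rng.lognormal(math.log(design.depth_mean * design.control_depth_scale), design.depth_dispersion))),
        )
        included = rng.random(n_taxa) < design.cross_contam_prob
        mock_w = np.where(included, design.cross_contam_weight, 0.0)
        probs = np.concatenate([mock_w, weights])
        probs = probs / probs.sum()
        columns.append(rng.multinomial(depth, probs))
        meta_rows.append(
            {"sample_id": f"NEG2_{c+1}", "role": "NEG2", "group": None, "replicate": None, "dna_quant": np.nan}
        )
        k += 1
    for c in range(design.n_pcr_controls):
        rng = sample_rngs[k]
        depth = max(
            1,
            int(round(rng.lognormal(math.log(design.depth_mean * design.pcr_depth_scale), design.depth_dispersion))),
        )
        probs = np.concatenate([np.zeros(n_taxa), weights])
        columns.append(rng.multinomial(depth, probs))
        meta_rows.append(
            {"sample_id": f"NEG1_{c+1}", "role": "NEG1", "group": None, "replicate": None, "dna_quant": np.nan}
        )
        k += 1

    counts = np.stack(columns, axis=1)
    table = FeatureTable(
        feature_ids=feature_ids,
        sample_ids=[r["sample_id"] for r in meta_rows],
        counts=counts,
        sequences=sequences,
        taxonomy=taxonomy,
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    return table, meta, truth, references
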