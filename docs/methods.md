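# Methods

## Data model and conventions

Feature tables are integer count matrices, features × samples, read and
written as TSV with the feature ID in the first column and optional
`sequence`/`taxonomy` columns recognised by name. Counts must be integers;
relative abundances `r(f,s) = count(f,s) / total(s)` are always derived on
the fly and never stored, so a table round-trips losslessly. A transposed
table is rejected rather than guessed. Samples with zero total reads are
retained but flagged; they contribute zeros to every mean (quality control,
not I/O, decides their removal). Sample roles come from a metadata TSV:
`sample` for biological samples, `NEG1`/`NEG2` for the two control types
(conventionally PCR and pipeline controls respectively); the filters treat
the roles as opaque labels and can be run independently per control type.
Nucleotide sequences are uppercased, `U` mapped to `T`, and restricted to
the four bases plus the eleven IUPAC ambiguity codes.

## Quality-control filters

Four pre-decontamination steps, composable in any order, with relative
abundances recomputed from the current table at each step (sequential
workflow semantics). Boundary conventions are fixed and tested:

| step | removes | boundary |
|---|---|---|
| read depth | biological samples with few reads | kept iff total **>** `min_reads` |
| max count | features never abundant anywhere (singletons at 2) | kept iff max count **≥** threshold |
| frequency | features never reaching a relative abundance | kept iff max abundance **≥** threshold |
| length | sequences far from the amplicon length | removed iff deviation **≥** tolerance |

The depth filter exempts controls by default (their low depth is expected
and they are needed downstream); a flag applies it globally. Each step
returns an accounting record whose read deltas are exact.

## Contaminant classifiers

The ratio statistic for feature *f* is
`mean_{c∈controls} r(f,c) / mean_{s∈samples} r(f,s)`, with both means taken
over *all* samples of the relevant role, zeros included — the span filter,
not the mean, is the tool for sporadic occurrence. Removal is strict
(`ratio > t`). When the sample mean is 0 and the control mean positive the
ratio is +∞ and the feature is removed at any finite threshold; a feature
absent from both is recorded as NaN and kept (no evidence). The span
statistic is the integer number of controls with a nonzero count; removal
at `span ≥ k`, `1 ≤ k ≤ n_controls`, displayed as "k of n". Count rather
than fraction semantics follow from the available thresholds being one per
control. Two exact consequences are asserted on random tables: span(k=1) ≡
presence, and ratio(t=0) ≡ presence (a feature occurs in a control iff its
control mean is positive, making the ratio positive or infinite).

Removal is always global — the feature row is dropped from every sample —
matching feature-level truth labels. Results from two runs (e.g. per
control type) combine by union or intersection of removal sets. External
tools enter through decision TSVs (`feature_id`, `decision`, optional
score) so their outputs can be scored by the same metrics without
re-implementing them; re-implementations of those tools are out of scope.

## Truth labeling

Features are labeled MOCK when their Levenshtein distance to some expected
reference sequence is at most `max_dist` (default 4), else CONTAMINANT; a
stricter exact-or-one-mismatch mode is provided for even-community
conventions. Distances are computed with edlib; the independent test oracle
is a hand-written full dynamic program. IUPAC tolerance makes a
substitution free when the two symbols' base sets intersect (N matches
anything, R matches A/G); insertions and deletions always cost 1. For
gene-scale references matched by shorter amplicons, `windowed=True`
switches to semiglobal (infix) alignment — the query is scored against its
best-matching stretch of the reference with free end gaps, the standard
infix distance for this task. Ties in best reference go to input order.

## Evaluation metrics

Positive class = CONTAMINANT, positive prediction = REMOVE (the
sensitivity definition — correctly removing contaminants — forces this).
From TP/FP/TN/FN: sensitivity, specificity, accuracy, baseline accuracy
`(TP+FN)/total` (contaminant prevalence; the accuracy of the
remove-everything classifier), precision, MCC, and Youden's index
`J = sensitivity + specificity − 1`. Feature-level weighting is the
default (each ASV counts once); read weighting multiplies each feature by
its total count within a chosen sample scope. Undefined values (precision
with nothing removed; sensitivity with no contaminant present) are carried
as NaN, never silent zeros; MCC alone uses the common zero-denominator → 0
convention. Precision–recall grids evaluate one filter family over a
threshold list, ordered by threshold, flagging undefined-precision rows.

## Simulator

The generator emulates a serially diluted mock community sequenced with
negative controls:

- **Contamination model.** Reagents contribute a constant effective load of
  λ = `contaminant_load_cells` per sample, so at input N cells the expected
  contaminant read fraction is λ/(N+λ) — the hyperbolic curve that makes
  low-biomass samples mostly contaminant reads. Default λ = 2×10⁶ cells,
  chosen so contamination is just under 2% at 10⁸ input cells and above 50%
  below 10⁶. Contaminant identities and relative weights are drawn once per
  dataset from a log-normal law (σ = 1.5, heavy-tailed), shared by all
  samples and controls: contaminants are systematic.
- **Controls.** Pipeline controls (NEG2) contain the contaminant pool at
  about a tenth of the samples' depth, plus sporadic cross-contamination:
  each mock taxon enters each pipeline control independently with
  probability `cross_contam_prob` at small relative weight. PCR controls
  (NEG1) are near-empty (0.5% of sample depth) and contaminant-only.
- **Counts.** Per-sample depth is log-normal around `depth_mean`
  (dispersion 0.2–0.3); counts are one multinomial draw per sample, so
  per-sample totals equal the drawn depth exactly.
- **Sequences.** Each mock taxon gets a random reference; its feature is
  the reference with at most 4 random edits. Contaminant sequences are
  random and verified to lie at least 8 edits from every reference, so
  distance-4 labeling recovers the planted truth with zero error by
  construction.
- **Determinism.** One integer seed feeds a seed sequence whose spawned
  substreams drive sequences, pool weights and each sample's draws; output
  is bit-identical for a given design.

Preset designs (all proportions sum to 1):

- **EVEN** — 8 taxa between 6% and 22% (endpoints fixed; six interior
  values linearly spaced and positioned so the total is exactly 1),
  threefold dilutions 1.5×10⁹ → ~2.3×10⁵ cells, one pipeline control,
  pool of 60 contaminants, depth 50 000, 253-bp references.
- **STAGGERED_A** — 15 taxa on a geometric series spanning exactly two
  orders of magnitude (max/min = 100), normalised; tenfold dilutions
  10⁹ → 10² in triplicate; 3 pipeline + 3 PCR controls; pool 50; depth
  14 000, controls ~10%; 362-bp references; cross-contamination rare
  (p = 0.02).
- **STAGGERED_B** — 3 taxa at 84.3/12.7/3%; dilutions 1.1×10⁵ and
  5.55×10³ in quadruplicate; 4 pipeline + 2 PCR controls; λ = 3×10³
  (a much cleaner buffer, giving ~3%/35% contamination at the two
  dilutions); heavy cross-contamination (p = 0.5, so a mock taxon is
  expected in 2 of 4 controls); pool 30; depth 25 000.

Depths and pool sizes are moderate working scales for a desk-size
benchmark; the simulator does not model PCR bias, chimeras, per-read error
profiles, or multiple ASVs per taxon, so passing benchmarks show the
filters' behaviour under the structural assumptions above, not performance
on any particular real dataset.

## Benchmark protocol

Filters are run separately per dilution group on that group's biological
samples plus all controls of the chosen role (controls are dataset-level;
they are not diluted), so sample means reflect only the group being tested.
Scores are computed per replicate over the features actually observed in
that replicate's sample (a feature with zero counts in a sample is no
evidence either way) and averaged over replicates — the mean of scores, not
of confusion counts. At very low input, replicates may contain no mock
features at all; their specificity and Youden are then undefined and the
group's aggregate is NaN rather than a fabricated value. For ground-truth-
free data, `reduction_summary` reports reads/features kept and
`top_taxa_shift` the mean per-taxon relative abundance over biological
samples before vs after filtering, the after-view renormalised over kept
features (closed compositional view, stated explicitly).

## Numerical and design choices

- Score aggregation ignores NaN replicates (`nanmean`); all-NaN groups stay
  NaN.
- Feature/sample order is preserved everywhere; filter decisions are
  invariant to sample permutation (tested).
- The benchmark's "frequency" family computes its maximum over biological
  samples only, since in a benchmark run the table also carries controls;
  the QC-step variant operates on whatever table it is given.
- Relative-abundance columns sum to 1 within 1e-9 for nonzero samples;
  comparisons involving ±∞ follow IEEE semantics (∞ > any finite
  threshold), with NaN ratios explicitly kept.

## Known limitations

- No BIOM/HDF5 containers and no taxonomy parsing into ranks; taxonomy is
  an opaque per-feature string.
- External tools are integrated only via decision files; their internal
  scores are not reproduced.
- The simulator's cross-contamination is independent per taxon and
  control; correlated leakage (e.g. plate neighbours) is not modelled.
- Read-weighted and feature-weighted scores can disagree under strong
  class imbalance; both are provided and neither is privileged beyond the
  feature-level default.
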