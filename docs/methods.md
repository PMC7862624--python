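# Methods

This note documents the models and procedures implemented in `fscm`, the
defaults and why they were chosen, and what the synthetic benchmark does and
does not demonstrate.

## The scoring card model

A scorecard assigns each of the 400 dipeptides (or 20 amino acids) a
propensity score PSᵢ on a 0–1000 scale.  A peptide *P* is scored as
S(P) = Σᵢ xᵢ·PSᵢ with *x* the **normalized** composition of the (possibly
region-sliced) peptide: dipeptide counts over the number of counted pairs, or
amino-acid counts over length.  Since Σxᵢ = 1, S(P) is a weighted mean of
scorecard entries and is length-independent, staying inside
[min PS, max PS] ⊆ [0, 1000].  This is the reading consistent with published
peptide scores of this family of models, where 5-mers and 23-mers occupy the
same few-hundred range; a raw-count variant (`score_peptide(...,
raw_counts=True)`), which scales with length, is retained for comparison.
Classification is strict: positive iff S(P) > threshold; a score equal to the
threshold is negative.

### Feature classes (regions)

Eleven feature classes are supported: whole-sequence amino-acid (APS) and
dipeptide (DPS) granularity, and dipeptide composition on the first/last 5,
10 or 15 residues (N5…C15) or the concatenation of both terminal windows
(N5C5, N10C10, N15C15).  Sequences shorter than a terminal window are used
whole (truncation) rather than dropped — no minimum length beyond 2 residues
is imposed, so every valid peptide is sliceable by every region.  For the
joined NC regions the junction pair (last N residue followed by first C
residue) is an artefact of concatenation; the default **includes** it — the
simplest literal reading of joining the termini — and every entry point takes
`include_junction=False` to exclude it, since the convention used by
published NC-composition features is not documentable either way.

### Initialization

Per class, dipeptide counts are pooled over all (region-sliced) training
sequences and normalized by the class total (NPS⁺, NPS⁻).  The raw propensity
is **NPS⁺ − NPS⁻** — the direction under which high scores mean
positive-class-like, matching the published worked example
(0.622 − 0.2 = 0.422) — then min–max scaled onto [0, 1000].  The endpoints are
pinned exactly (the minimum maps to 0.0, the maximum to 1000.0, not to values
a few ulp away).  Degenerate cases: a constant raw vector maps to the
direction-neutral midpoint 500 everywhere; dipeptides absent from both
classes score raw 0 with no pseudocounts.  Label swap is an exact
antisymmetry: swapped-class normalized scores equal 1000 minus the originals.

### Genetic-algorithm refinement

The GA maximizes F = w₁·AUC + w₂·R (defaults 0.9/0.1).  AUC is the
Mann–Whitney statistic (ties half-credit) of the candidate's training scores,
either averaged over a seeded stratified 10-fold partition of the training
peptides (default; nothing is refit per fold — the candidate scores are
global, so folding only averages the ranking statistic over subsamples) or
computed on the whole training set (`full_set_auc=True`, faster and
equivalent in how it ranks candidates).  R is the Pearson correlation between
candidate and initial scores, clipped to [−1, 1] so floating-point round-off
cannot rank a duplicate of the initial vector above it; a constant candidate
gets R = 0 with a warning.

The GA itself is a standard real-valued scheme, fully specified by
`GAConfig`: population 100 (one individual is the exact initial vector, the
rest initial + N(0, σ) noise), 50 generations, tournament selection (size 3),
uniform crossover (rate 0.8), per-gene Gaussian mutation (rate 0.05, σ = 50
on the score scale), elitism 1, clipping to [0, 1000] after mutation so the
refined card stays on the initial card's scale.  The best-so-far fitness
trace is non-decreasing by construction.  The decision threshold is **not**
part of the chromosome; it is fitted post hoc on training scores.  Ten
independent runs with derived seeds (`multi_run`) mirror the practice of
generating several refined scorecards and keeping the best by fitness.

### Threshold selection

No published rule exists for the reported thresholds, so the package uses the
transparent one: the cutoff maximizing training accuracy over a candidate
grid consisting of the midpoints of adjacent sorted unique scores plus two
boundary cutoffs (just below the minimum — predict everything positive — and
at the maximum — predict everything negative under the strict rule).  The
boundary cutoffs guarantee the selected threshold is never worse than the
majority-class predictor.  Ties go to the lowest cutoff, favoring
sensitivity.

### Evaluation

Ac, Sn, Sp and MCC use the universal confusion-matrix definitions; MCC with a
zero denominator is reported as 0 with a warning.  ROC AUC is the
Mann–Whitney statistic (scikit-learn's implementation; an exhaustive pairwise
oracle in the test suite confirms exact agreement, ties included), and the
trapezoidal integral of the swept ROC curve agrees with it to 1e−9.  The
cross-validation protocol builds the initial card on each fold's training
part, optionally GA-refines it, fits the threshold on fold-training scores,
and evaluates on the held-out fold.

## Physicochemical property analysis

Amino-acid propensities derive from a dipeptide card by averaging, for each
residue r, the 40-slot multiset {rX : X} ∪ {Xr : X} (the homopair rr counts
twice; this makes exactly 40 summands).  Property records are AAindex-style:
20 per-residue values; records with any missing (NA) value are excluded on
load.  Correlation is Pearson's R on property **values** (printed ranks in
reference tables are presentation only), and selection uses the strict rule
|R| > 0.5.  Correlations are computed at the stored precision of the packaged
reference columns (two decimals), which reproduces the published correlations
for the amphiphilicity (MITS020101, R = 0.577) and alpha-helix (QIAN880113,
R = 0.569) indices exactly.  For the hydrophobicity index JOND750101 the
correlation computed from the published table's own values is 0.451 — the
published 0.541 appears to be a transposition — and under the strict rule
0.451 does not pass the 0.5 cutoff; the package reports the computed value.

## Synthetic benchmark

The generator emulates the one structure the method exploits —
class-discriminating adjacent residue pairs — with everything else
exchangeable between classes.  Positives are sampled from a first-order
Markov chain over the 20 residues whose transition weight for pair (a, b) is
the background probability of b multiplied by `effect_size ** weight` for
enriched pairs (divided for depleted); negatives come from the pure
background chain; the first residue of every sequence is background-drawn.
Defaults: 200 positives + 200 negatives, lengths uniform on 10–30, uniform
background, enriched pairs {KK, LW, GH}, effect size 5, seed 7.  Each
sequence uses a counter-derived RNG substream, so datasets are stable under
reordering or resizing of the other class.

The per-pair enrichment **weight** defaults to 4.  Rationale: with only three
planted pairs among 400 and ~19 pairs per peptide, a mild multiplier leaves
the two classes nearly indistinguishable in principle (at a ×5 transition
multiplier the Bayes accuracy ceiling is ≈ 0.66 — no scorecard can recover
what is not there).  Weight 4 puts the planted transitions at
effect⁴ ≈ 625× background at the default effect size, so a source residue
emits its planted partner ~99% of the time and the held-out recovery of the
pipeline (accuracy ≈ 0.92) is a sharp test of the scorecard machinery rather
than a coin flip.  The exponential form keeps `effect_size = 1` an **exact
null** (classes exchangeable; cross-validated AUC ≈ 0.5), used for
calibration checks, and makes signal strength monotone in effect size.

What passing on this benchmark does **not** show: real anticancer peptides
are not first-order Markov chains; their discriminative signal is weaker,
spread over many features, length-correlated and terminally localized.
Synthetic recovery validates the estimator and optimizer mechanics, not
benchmark-level accuracy.  Reproducing published benchmark figures requires
the public ACP datasets (downloadable FASTA pairs usable directly with
`fscm train`) and depends on an unpublished GA configuration; expect
agreement in ranking of feature classes rather than in exact table values.

## Numerical and design choices

- Canonical ordering everywhere: residues alphabetical, dipeptides
  lexicographic; serialized scorecards carry explicit symbol labels so files
  never depend on the in-memory ordering.
- All randomness flows through `numpy.random.default_rng` seeded from a
  single master seed per operation; GA runs, fold partitions and synthetic
  datasets are bit-reproducible for a fixed seed.
- Stratified splitting keeps both sides non-empty per class and errors on
  classes smaller than 2; fold partitions error when folds exceed the
  smaller class.
- Scores are stored at full precision (`repr`) in TSV scorecards; display
  rounding is two decimals.
- Problem sizes in the test suite and acceptance script match the synthetic
  defaults (400 peptides; GA at population 100 × 50 generations with
  whole-set AUC fitness), which keeps every check exact to the stated study
  conditions while running in seconds.

## Known limitations

- The GA scheme is a documented standard choice, not a reconstruction of the
  original unpublished configuration; fitness values are comparable only
  within this implementation.
- The threshold rule is transparent but not provably the published one;
  thresholds on real data will differ from published tables.
- Terminal-window truncation for short peptides is this package's
  convention; other implementations may drop or pad such sequences.
- The packaged property fixture contains three reference columns, not the
  full AAindex; full-database analyses require an external property table in
  the documented flat TSV format.
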