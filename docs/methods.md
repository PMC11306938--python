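# Methods

## The prediction problem

Transcription factors (TFs) are DNA-binding proteins that regulate
transcription. Given only a protein's primary sequence, the package decides
TF vs non-TF by fusing two independent lines of evidence:

1. **Alignment-free arm.** The sequence is encoded by its amino-acid
   composition (AAC), its dipeptide composition (DPC), or their
   concatenation, and a supervised classifier converts the encoding into a
   positive-class probability `p ∈ [0, 1]`.
2. **Alignment-based arm.** The query is searched against a labelled
   reference database of training sequences; the class of the top hit
   (lowest e-value, ties broken by higher bit score, then subject id) is
   transferred to the query, or NO_HIT when nothing passes the e-value
   cutoff.

The **hybrid score** is the sum `p + v`, where the vote `v` is `+w` for a
TF top hit, `−w` for a non-TF top hit and `0` for NO_HIT. The final label
is TF iff the decision score is at or above the threshold.

## Feature encodings

For a sequence of length `L` over the 20 standard residues
(fixed alphabetical order `ACDEFGHIKLMNPQRSTVWY`):

- `AAC_i = R_i / L`, the fraction of residue type `i` (20 values, sum 1);
- `DPC_i = D_ij / (L − j)`, the fraction of ordered residue pair `i` among
  the `L − j` positional pairs at gap `j` (400 values, sum 1 when
  `L > j`); the standard adjacent-pair composition is `j = 1`, the
  default, and the gap is exposed as a parameter;
- their concatenation, AAC block first (420 values);
- one-hot: each residue becomes a 21-slot indicator row — 20 slots by
  alphabetical index plus one dummy slot that is never set; any
  non-natural symbol (X, B, Z, …) maps to the all-zero row. Sequences are
  right-truncated at `max_len` (default 1,000) and zero-padded below it.

Fractions are the canonical internal scale; percent is a presentation
option (class-composition summaries report percent). The 21st one-hot slot
is retained for format compatibility but intentionally unused, mirroring
the all-zero treatment of unknown residues.

## Curation rules

- **GO labelling**: an entry is a TF if it carries a TF-activity GO term,
  or both a DNA-binding term and a transcription-regulation term. Terms
  are matched as flat sets against user-supplied id lists; there is no
  ontology-graph traversal.
- **Non-natural filter**: sequences containing any residue outside the 20
  standard amino acids are dropped from training data. At *prediction*
  time such sequences are instead flagged and scored with composition
  computed over their natural residues only (with `L` the natural-residue
  count), since a prediction service should not reject arbitrary input.
- **Redundancy removal**: exact-sequence duplicate removal, first
  occurrence kept. No similarity-threshold clustering is performed; with
  no stated identity cutoff, exact identity is the only defensible
  reading.
- **Stratified split**: per class, `round_half_up(f · n_class)` records go
  to train after a seeded shuffle. With `f = 0.8` and 19,406 positives
  this yields 15,525 train / 3,881 test positives. (Published counts for
  this corpus quote 15,525 / 3,882, which sum to one more than the corpus
  size; the rounding rule here is stated exactly so the arithmetic is
  reproducible.) The seed is a mandatory argument — no hidden global RNG.

## Classifiers and model selection

Eight families are available: decision tree, random forest, extra trees,
gradient boosting (bound to XGBoost), k-nearest neighbour, Gaussian naive
Bayes, logistic regression and support-vector classifier (Platt-calibrated
via `CalibratedClassifierCV(SVC(), ensemble=False)`, since the SVM has no
native probabilities). Every family is deterministic for a fixed seed. The
production default is **extra trees on AAC** (200 trees), the
configuration that wins the alignment-free comparison; all families remain
selectable for comparative studies.

Cross-validation is stratified k-fold (default k = 5) with an explicit,
seed-driven fold assignment: within each class the row indices are
shuffled by the seed and dealt round-robin to the folds, so the partition
depends only on `(n, y, k, seed)`. Reported CV performance is the
arithmetic mean of the per-fold reports. Grid search enumerates the full
Cartesian product of the grid in deterministic order (sorted parameter
names), scores each combination by the mean CV metric (AUC by default) and
breaks ties toward the first combination. The shipped default grids are
editable starting points, not tuned values.

## Similarity search

The reference database is the labelled training set. Two engines satisfy
the same search contract:

- **blast** (default when available): external NCBI BLAST+
  (`makeblastdb` + `blastp`, tabular output, default scoring parameters).
- **pairwise**: an in-process local aligner (BLOSUM62, gap open −11 /
  extend −1) whose raw scores are converted to bit scores and e-values
  with the Karlin–Altschul gapped BLOSUM62 constants (λ = 0.267,
  K = 0.041) and the search-space size `m × N` (query length × total
  database residues). It needs no external binary but is quadratic in
  sequence count, so it is intended for small datasets and testing.

E-value sweeps run one search at the loosest cutoff and filter per cutoff.
Because the e-value of a hit does not depend on the reporting threshold,
this is equivalent to independent runs while guaranteeing structurally
that the NO_HIT count is non-increasing as the cutoff relaxes. The
percent-correct statistic of a sweep uses the hits-only denominator:
queries with no hit are tabulated separately rather than counted as
errors, because coverage and accuracy of annotation transfer are distinct
failure modes.

The default cutoff grid is 1e−6 … 1e−1, 1, 10, 100, 200, 1000.

## Fusion constants

Vote weight `w = 0.5` and decision threshold `0.5`, both configurable. At
these defaults a confident agreeing hit is decisive — `p + 0.5 ≥ 0.5` for
any `p` — while NO_HIT defers entirely to the classifier, and a
disagreeing hit vetoes a weak classifier score. Ties at the threshold go
to TF. In `blast` mode NO_HIT falls back to non-TF (the conservative call
for the rare class).

## Evaluation parameters

With TF positive: sensitivity `100·TP/(TP+FN)`, specificity
`100·TN/(TN+FP)`, accuracy `100·(TP+TN)/n`, `F1 = 2TP/(2TP+FP+FN)`,
Matthews correlation coefficient with the standard square-root-of-marginal-
products denominator, Cohen's kappa `(p_o − p_e)/(1 − p_e)` from the
confusion marginals, and AUC as the midrank Mann–Whitney statistic
(ties counted half; identical to trapezoidal ROC integration). Degenerate
denominators (a ratio whose denominator is zero, including the MCC's and
kappa's) return 0 rather than raising, so sweeps over extreme thresholds
remain total. An all-zero confusion matrix is an error.

## Synthetic data generator

The generator emulates the two signals the method exploits, and nothing
else:

- **compositional bias**: residues are drawn i.i.d. from the uniform 1/20
  background with `+bias_delta` probability added to the
  class-characteristic residues (E, P, Q, R, S for TF-like; A, G, I, V
  for non-TF-like), renormalized;
- **homologous families**: founders are expanded into families of
  `family_size` point-mutated copies (per-site substitution probability
  `mutation_rate`, uniform over the other 19 residues, length preserved),
  and a family inherits its founder's class as a unit — so top-hit label
  transfer is label-consistent by construction.

Defaults, chosen once as the package's study conditions: 1,000 sequences
per class, lengths uniform in 80–300, `bias_delta = 0.04`,
`family_size = 5`, `mutation_rate = 0.05`. At 5% divergence family members
are found by BLAST at the strictest default cutoff (1e−6), giving the
alignment arm realistic signal; at `bias_delta = 0.04` the composition
classes are well separated, so extra trees on AAC reaches held-out AUC
close to 1 and the suite's ≥ 0.90 recovery bound has margin.

What the generator does **not** model: motif or domain structure, real TF
domain architectures, organism mixtures, Swiss-Prot length distributions,
or homology between the two classes. Passing tests therefore demonstrate
that the mechanism works — encoders are exact, arms carry their intended
signal, fusion never hurts ranking when the reference labels are sound —
not that any particular accuracy will be achieved on real proteomes.
A companion negative control scrambles the reference labels and asserts
that the hybrid advantage disappears.

## Numerical and procedural choices

- Round-half-up per class in the stratified split (documented above).
- Top-hit ordering is a total order (e-value, −bitscore, subject id), so
  calls are deterministic for a fixed engine version.
- Feature matrices are pandas DataFrames with named columns (A…Y, AA…YY);
  a trained model stores its column list and rejects matrices whose
  columns differ, preventing silent feature misalignment.
- Model archives store the spec, fitted estimator, feature names and a
  SHA-256 fingerprint of the training inputs.
- Problem sizes in the test suite and the acceptance script are the
  generator defaults (2,000 sequences, 80/20 split); the five-seed
  recovery check reuses those conditions per seed.

## Known limitations

- The pairwise fallback engine's e-values use ungapped-style
  Karlin–Altschul scaling with fixed gapped constants; they agree with
  BLAST qualitatively (self-hits ≪ 1e−6, unrelated pairs ≫ 1) but not
  numerically.
- Cohen's kappa is the assumed chance-corrected agreement statistic for
  the K column of the report layout.
- The hits-only denominator choice for sweep accuracy is a documented
  convention, not the only possible reading.
- No probability calibration beyond each model's native scores (except
  the SVM, which requires it); hybrid score addition assumes the ML score
  is on a [0, 1] probability scale.
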