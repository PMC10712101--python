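# Methods

## Problem setting

Given a protein and a lysine position, decide whether the site carries a
glutaryl modification. Supervision comes as site annotations (protein id,
1-based lysine position, binary label); the classifier never sees the full
protein, only a fixed window of 16 residues on either side of the lysine
(length 33), with positions beyond the protein termini filled by the
placeholder `X`. All coordinates in the package are 1-based inclusive.

## Feature encoders

Seven row-aligned blocks are computed per window; their widths are fixed
contracts checked by the test suite.

- **BE (726).** One-hot over the ordered 22-letter alphabet
  `ACDEFGHIKLMNPQRSTVWYUX` (20 standard residues, selenocysteine `U`,
  placeholder `X`), 22 bits per position.
- **EAAC (580).** For each of the 29 sliding windows of width 5, the
  frequency `f(t, win) = N(t, win)/5` of each of the 20 standard residues.
  `U` and `X` count toward no numerator, so frequencies on padded windows
  sum to less than 1 — deliberately, as padding carries no composition
  signal. The width follows directly from the formula:
  (33 − 5 + 1) × 20 = 580.
- **CKSAAP (484).** Frequencies of the 484 ordered residue pairs at gap
  k = 0, denominator `N_total = 33 − k − 1`, so the vector always sums to 1.
- **CTDC (39).** For each of 13 physicochemical partitions of the 20
  standard residues into 3 groups (seven hydrophobicity scales, van der
  Waals volume, polarity, polarizability, charge, secondary-structure
  propensity, solvent accessibility — the standard CTD grouping table,
  shipped as package data), the fraction of window residues in each group.
  `U`/`X` are excluded from the denominator.
- **BLOSUM62 (660).** Each position's 20-entry substitution-score row from
  the published BLOSUM62 matrix; `U` and `X` rows are all-zero.
- **STRUCT (66).** The 33-letter secondary-structure window (coil C,
  helix H, strand E, padding/unknown X) through the fixed 2-bit codebook
  C→00, H→01, E→10, X→11. Input files using `O` for strand are normalized
  to `E`.
- **PSSM (660).** The 33 rows of the protein's L×20 PSI-BLAST
  position-specific scoring matrix around the site, zero-padded outside
  the protein. The parser takes the first 20 numeric columns (log-odds) of
  the ASCII `-out_ascii_pssm` dialect and records the file's own residue
  column order; columns are never silently reordered. Values outside the
  typical [−15, 13] range are accepted with a warning.

Assembled width with all blocks: 3,215. STRUCT and PSSM are optional (they
depend on external predictions) and are omitted when annotations are
absent.

Normalization is per-column min–max fitted on training rows only; constant
columns map to 0, and test values outside the training range are not
clipped (they are legitimate extrapolations the tree model handles).

## Class balancing

Down-sampling only: the minority class is never altered. All distances are
Euclidean on the normalized matrix — normalizing first keeps wide-range
blocks (PSSM) from dominating the metric. Rules, with every ranking tie
broken by ascending original index (making results deterministic and
permutation-equivariant):

- **NearMiss-1** keeps the majority rows with the smallest mean distance
  to their k nearest minority rows.
- **NearMiss-2** keeps those with the smallest mean distance to their k
  farthest minority rows.
- **NearMiss-3** is two-phase: each minority row nominates its k nearest
  majority rows as candidates; candidates are ranked by mean distance to
  their k nearest minority rows, largest first, and the top `n_keep` are
  retained (topped up from non-candidates under the same ranking if the
  candidate union is too small). The two-phase form is adopted because the
  one-sentence verbal rule underdetermines behavior when the candidate
  union differs from `n_keep`.
- **Random under-sampling** draws uniformly without replacement.

`k` defaults to 3 (the common convention); the default target is a 1:1
class ratio. Balancing applies to the training partition only — the
independent test set always keeps its native imbalance. On small
instances every variant is verified against an independent brute-force
execution of its rule.

## Feature selection

Elastic Net (`α = 10⁻⁶`, `l1_ratio = 0.5` by default) regresses the 0/1
label on the normalized, balanced training matrix; features with exactly
nonzero coefficients survive. No epsilon threshold is applied — the L1
term produces exact zeros, and "nonzero" is taken literally from the
coordinate-descent solver. The default alpha is nearly unpenalized and
prunes only redundant columns; the number of surviving features is
dataset-specific, not a contract. `l1_ratio = 0.5` is the symmetric
default since nothing favors either penalty; it is exposed as a flag.
Convergence warnings at tiny alphas are suppressed deliberately: the
selected support is stable well before the coefficient values fully
converge. `alpha_sweep` refits from scratch at each penalty (no warm
starts) so rows are exactly reproducible as single fits.

## Classifier and evaluation

`GradientBoostingClassifier` (scikit-learn) provides the boosted CART
ensemble; the package's contribution is everything around it. Grid search
covers (n_estimators, max_depth, learning_rate) with all other
hyperparameters at library defaults; folds are stratified (with a
balanced training set this is nearly neutral, but safer), the criterion
is mean held-out-fold AUC, and ties prefer fewer trees, then shallower
trees, then smaller learning rate. The reference operating point
(200 trees, depth 6, learning rate 1.0) is inside every shipped grid; a
learning rate of 1.0 is aggressive for gradient boosting but is retained
as a searchable value rather than hard-coded.

Metrics are evaluated exactly from the confusion matrix; conventions for
degenerate cases: Sen/Pre/F1 with empty denominators are 0, and MCC is 0
whenever any factor of its denominator is 0. AUC is the normalized
Mann–Whitney statistic with ties counted ½ (verified against O(n²) pair
enumeration). Probabilities at or above the 0.5 threshold map to the
positive class.

The full search grid (4×3×3) is the CLI default. Corpus-scale runs in the
test suite and acceptance script use a compact 2×2×1 subgrid
(`STUDY_GRID`) that brackets the reference operating point: exact-split
GBDT on ~3,000 features costs 10–20 s per fit, so the full grid's 180
cross-validated fits are a batch job, not a desk-scale check, and the
compact grid selects the same neighborhood.

## Two-sample logo

For every (window position, standard residue) cell, per-sequence presence
indicators are compared between positive and negative sets with a
pooled-variance two-sample t-test (the convention of two-sample-logo
displays; with 0/1 data this is equivalent to a two-proportion test up to
the variance estimator). Zero pooled variance is resolved as p = 1 when
the class means agree and p = 0 otherwise. Cells at p ≤ 0.05 with positive
delta are "enriched", negative delta "depleted". No multiple-testing
correction gates the display — matching standard two-sample-logo practice
— but a Bonferroni-adjusted column is exported for transparency. The
invariant center lysine is reported like any other cell and is
non-significant by construction. Under the null, the empirical
false-positive rate of the machinery tracks α ≈ 0.05 (measured at ~0.046
over seeded replications; the t-approximation on Bernoulli indicators is
slightly conservative at moderate n).

## Synthetic data generator

`generate_peptolome` emulates the statistical shape of a curated Kglu
corpus: one K-centered site per host protein, a configurable
negative:positive ratio (default 6.18 ≈ 4369/707), uniform background
residue composition (a composition vector can be supplied), and a planted
positional motif for positives. The default motif follows the
qualitative enrichment pattern reported for glutarylation flanks — lysine
enriched at flank positions 2, 7, 8, 10, 22–24, 26 and 33; L/D/E enriched
at scattered positions; F/N/P/M depleted downstream — with deliberately
large effect sizes (K probability ≈ 0.26 at enriched positions vs 0.05
background) so the signal constitutes a strong, unambiguously recoverable
planted effect. The effect sizes are NOT calibrated to real data; the
end-to-end tests demonstrate that the pipeline recovers a planted signal
and does not hallucinate one under the null, nothing more. Real protein
features the generator does not emulate: non-uniform residue composition,
sequence homology between proteins, multiple sites per protein,
evolutionary structure in PSSMs (fake profiles are noise biased toward
the identity column), and any dependence between sequence, structure and
profile blocks.

Windows are embedded in host proteins with random flanking context, and
~15% of sites per side sit within 16 residues of a terminus so the
padding paths are exercised. Fake PSSMs are integer matrices clipped to
[−15, 13]; secondary structure is a sticky three-state Markov chain
(stay probability 0.8) so states form runs as in real assignments.
Everything derives from a single seed; identical seeds give byte-identical
written corpora.

## Shipped problem sizes

The corpus-scale checks generate 707 + 4,369 sites (matching the split
arithmetic: a 25% stratified hold-out of 1,269 windows with 177 positives,
training negatives 3,277, NearMiss-3 balancing to 1,060 rows) and run the
end-to-end recovery at 530 positives / 3,277 negatives with the compact
grid; the null guard runs at 400/400 with the reference parameters. At
the null guard's test-set size (100 + 100), chance AUC has a standard
error of ≈0.04, so its [0.45, 0.55] acceptance band is intentionally
tight relative to sampling noise; it is evaluated at a fixed seed.

## Known limitations

- The EAAC width (580) and the audited total width (3,215) are the
  formula-consistent values; published descriptions of this feature
  recipe sometimes quote slightly different totals whose block arithmetic
  is not mutually consistent.
- Which 13 CTD properties "the" standard set contains varies across
  implementations; the iLearn-lineage table shipped here is one canonical
  choice.
- NearMiss distances on raw vs normalized features is a genuine free
  choice; normalized is implemented (and arguably the only defensible
  option when blocks have wildly different ranges).
- Elastic Net is fit on the balanced training matrix (balancing precedes
  selection in the pipeline); fitting on the unbalanced matrix is equally
  defensible and reachable through the library API.
- The GBDT itself is a library implementation; bit-level reproducibility
  holds within a scikit-learn version but not necessarily across
  versions.
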