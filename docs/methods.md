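# Methods

## Problem and model

`dbpstack` predicts whether a protein binds DNA from three per-protein
inputs: its amino-acid sequence, a PSI-BLAST position-specific scoring
matrix (PSSM; L×20 log-odds, one row per position, one column per residue
type), and a predicted 3-state secondary-structure probability profile
(L×3: helix, strand, coil). Four encoders map these variable-length inputs
to fixed-length feature blocks; per-block base classifiers are combined by
a logistic-regression meta-learner (stacked generalization).

### PSSM normalization

Each residue-type column of the PSSM is z-scored over the L positions
using the **population** standard deviation; a column with zero spread
becomes all-zero. Normalization is applied before both evolutionary
encoders. The row-wise reading of the same transformation is a plausible
alternative; the column-wise convention was chosen because the segmented
descriptor's per-segment column means are only informative when columns
are centered over the whole profile.

### Local segmented descriptor (`local_dpp`)

The normalized profile is split into `n` row segments: the first `n − 1`
segments have `floor(L/n)` rows, the last takes the remainder. Each
segment contributes 20 column means and, for each residue type and lag
`ξ = 1..λ`, the average squared difference between scores ξ apart
(divisor `segment length − ξ`). Total dimension `20(1 + λ)n`; both
headline configurations (`n=2, λ=2` and `n=3, λ=1`) give 120. Layout is
segment-major (means, then lag terms residue-major), so the whole equals
the concatenation of per-segment descriptors. `λ` must be smaller than
the shortest segment.

### Wavelet descriptor (`pssm_dwt`)

Each normalized column is a 1-D signal decomposed by a 4-level discrete
wavelet transform; level *i + 1* decomposes level *i*'s approximation
band. Per level, 13 features: max, min, mean and population std of the
approximation band and of the detail band (8), plus the first 5 detail
coefficients (zero-padded when the band is shorter). 52 per column, 1040
total. The wavelet family and boundary handling are configurable; the
defaults are Haar with half-sample symmetric padding, recorded in model
metadata. The split of the 13 per-level values (8 band statistics + 5
leading detail coefficients) and the choice of the detail band for the
leading coefficients are design choices of this package; both printed
counts (52 per residue type, 1040 total) follow from them. Signals
shorter than 2^levels stop the recursion early and missing levels
contribute zero features (logged); with the minimum realistic protein
length of 50 this arises only in synthetic corner cases.

### Composition descriptor (`d188`)

20 amino-acid frequencies (alphabetical order), then for each of eight
physiochemical properties whose three residue classes partition the
alphabet (hydrophobicity, van der Waals volume, polarity, polarizability,
charge, surface tension, secondary-structure propensity, solvent
accessibility): 3 class frequencies, 3 between-class adjacent-pair
transition frequencies (unordered pairs, divisor L − 1; within-class
adjacencies are not counted), and 15 distribution values — per class the
1-based positions of the first, `ceil(0.25c)`-th, `ceil(0.5c)`-th,
`ceil(0.75c)`-th and last occurrence divided by L (absent class: five
zeros). 20 + 8×21 = 188 total, every value in [0, 1]. An alternative
reading of the distribution component — class frequencies within five
equal sequence chunks — is available via `distribution="chunks"`; the
occurrence-percentile variant is the default because it is the classic
CTD-D form and produces exactly 15 values per property.

### Structure descriptor (`ac_struct`)

Auto-covariance of each state's probability series:
`AC(λ, j) = (1/(L−λ)) Σ_i (s_ij − mean_j)(s_{i+λ,j} − mean_j)` for
lags 1..l_min − 1 with l_min = 50 (the minimum accepted protein length),
then the 3 state means and 3 population standard deviations: 147 + 6 =
153. Cross-covariance between different states is deliberately excluded;
the 49×3 dimension count only fits the pure auto-covariance reading.
`l_min` is configurable for short synthetic toys; the feature length then
follows the closed form `3(l_min − 1) + 6`.

## Stacking

Base models are every (classifier, feature block) pair for the chosen
family: {svm}, {svm, rf}, {svm, rf, nb} → 4, 8, 12 models. Features are
standardized (train-fold statistics) before the SVM and the Gaussian NB;
the random forest is unscaled. Hyperparameters are selected by grid
search on stratified 5-fold CV accuracy; the full grids are
C ∈ {2⁻⁵..2¹⁵ ×4}, γ ∈ {2⁻¹⁵..2³ ×4} for the SVM and
trees ∈ {100, 300, 500}, max-features ∈ {sqrt, log2},
min-leaf ∈ {1, 3, 5} for the forest. The package also ships a reduced
`small_grid` (C ∈ {1, 32}, γ = scale; 100 trees) used by the test suite,
the CLI default and the acceptance script; it is the package's desk-scale
configuration and grid width does not change any of the structural claims
being tested.

Meta-features are the base models' positive-class probabilities, produced
**out-of-fold** (stratified 5-fold) so the meta-learner never sees
in-sample optimism; an in-sample mode exists behind a flag for
comparison. Fold models reuse the grid point chosen on the full training
split by default (`freeze_grids=True`); full per-fold re-search is
available. The meta-learner is maximum-likelihood logistic regression with
a ridge of 1e-6 on the slopes (never the intercept), whose only purpose
is a finite optimum under perfect separation; separation triggers a
logged warning. Classification threshold is 0.5 with ties going positive.
Majority voting over the four single-block classifiers is provided as a
baseline: strict majority, ties broken by mean positive probability.

## Evaluation

SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total, and MCC with the
four-factor product under one square root; any metric with a zero
denominator is defined as 0. Schemes: stratified k-fold (per-fold +
pooled), leave-one-out (pooled confusion counts only — per-fold metrics
are undefined for single held-out samples), and repeated r×k CV reporting
mean ± population std of each metric across run-level results. Every fold
trains a complete stacked model; the per-fold meta-coefficients feed a
one-sample two-sided t-test against zero per base model, reported with
`distance = α − p` (α = 0.05). Zero coefficient spread with nonzero mean
is reported as p = 0 with a degenerate-variance flag.

## Synthetic data

The generator emulates the three inputs with a tunable class signal:

- sequences i.i.d. over the alphabet, positives biased toward a fixed
  5-residue subset (R, K, D, E, Q) by `comp_effect`;
- PSSM entries are N(0, noise_sd²); positives additionally receive
  `pssm_effect` on the five designated columns **over the first half of
  the sequence only**. The localization matters: the evolutionary
  encoders z-score each column, so a column-wide constant shift would be
  normalized away entirely, whereas a half-sequence shift survives as
  segment-mean contrast (picked up by `local_dpp`) and low-frequency
  structure (picked up by `pssm_dwt`) — a crude stand-in for a localized
  binding region;
- secondary structure follows a 3-state Markov chain (stay probability
  0.7) whose helix persistence grows with `ss_effect` for positives; each
  row assigns ~0.85 mass to the current state plus uniform noise and is
  normalized.

Defaults: 100 positives + 100 negatives, lengths uniform on [50, 120],
noise_sd = 1, all effects 0 (the null configuration, under which the two
classes are exchangeable). The planted-signal experiments in the test
suite use `pssm_effect = 3 × noise_sd` at n = 200. The writer emits the
PSI-BLAST ASCII dialect with log-odds rounded to 2 decimals and `.ss2`
probabilities to 3 decimals, so round trips are exact to format precision
(5×10⁻³ / 2×10⁻³), not bitwise.

What the generator does **not** emulate: residue-residue dependencies and
homology structure in sequences, the alignment-depth-dependent column
correlations of real PSI-BLAST profiles, and the systematic errors of
real secondary-structure predictors. Passing tests therefore demonstrate
the correctness and the qualitative behavior of the pipeline (signal
routing, calibration under the null, coefficient attribution), not
benchmark-level accuracy on real proteome data, which additionally
depends on profile quality.

## Numerical conventions and edge cases

- Population (1/N) standard deviations throughout the feature encoders.
- Feature tables are TSV with shortest-round-trip float repr: read(write(x))
  is bit-exact.
- `.ss2` rows are renormalized on load; deviations beyond 0.05 from unit
  sum, or negative probabilities, are rejected.
- FASTA entries containing non-standard residues are skipped with a
  warning (batch processing continues); empty files are format errors.
- Single-row PSSMs cannot be normalized (no spread) and are rejected.
- Prediction with a persisted model refuses explicitly requested feature
  parameters that differ from the training metadata, even when the
  dimensionalities coincide (the two headline `local_dpp` configurations
  both have 120 dimensions but are not interchangeable).
- Seeds propagate from a single integer through scikit-learn splitters
  and numpy generators; identical seeds give bit-identical models,
  reports and synthetic datasets.

## Problem sizes in the shipped experiments

The test suite and acceptance script run at desk scale: planted-signal
experiments at n = 200 over 10–20 seeds, null calibration pooled over two
n = 200 runs, oracle-equivalence checks at 100 random instances per
operation, and exhaustive metric enumeration up to 12 samples. These
sizes are the package's chosen test conditions; all structural claims
(dimension identities, oracle equality, layout properties) are
size-independent.

## Known limitations

- Real-data benchmark performance requires genuine PSI-BLAST and PSIPRED
  profiles, which the package parses but does not produce.
- The SVM's Platt-scaled probabilities are themselves cross-validated
  estimates and can be slightly miscalibrated on tiny training folds.
- The in-sample meta-training mode is provided for comparison only; it
  leaks base-model optimism into the combiner and should not be used for
  reported results.
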