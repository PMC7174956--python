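# Methods

## Profile input and normalization

The unit of input is the match-emission block of a profile HMM in HHsuite
`.hhm` format: for a protein of length `L`, an `L x 20` matrix of integer
scores in units of `-1000 * log2(p)`, with `*` marking probabilities too
small to store.  The parser consumes the flat v2/v3 dialect — from the
`HMM` column-header line to the `//` terminator — taking only the first
line of each two-line match-state record (20 emission scores) and ignoring
the NULL model, insert/delete transitions and per-state diversity values.
The amino-acid column order is taken from the file header and carried
through every downstream computation; it is never re-sorted, so feature
indices are stable even for files with a non-standard column order.
Residue letters are retained for diagnostics only.

Scores are mapped to probabilities by `f(*) = 0`, `f(x) = 2^(-x/1000)`;
no further rescaling or clipping is applied.  `f` is strictly decreasing on
integer scores, so score order is preserved in probability space, and
`*` positions are exactly zero.

## AATP features

- **AAC** `x_j = (1/L) Σ_i h[i][j]` (20 features).  Bounded in [0, 1];
  if every profile row sums to `s`, the AAC components sum to `s` exactly.
- **TPC** `y[i][j] = Σ_{k=1..L-1} h[k][i] h[k+1][j]`, normalized by the
  row sum over `j` (400 features).  Each row of the 20 x 20 matrix is a
  probability vector over the successor amino acid; `L >= 2` is required.

Rows whose normalization denominator is zero (amino acid `i` has no
emission mass anywhere in positions `1..L-1`) are left **all-zero** rather
than filled uniformly: zero evidence is encoded as zero signal, and the map
stays deterministic.  Users comparing against a uniform-fill convention
should note this choice.

The fused vector is AAC first, then TPC flattened row-major (predecessor
outer, successor inner) — 420 components with deterministic names
`AAC_<aa>`, `TPC_<aa_i>_<aa_j>`.  The component order is fixed here for
reproducibility of serialized models; nothing downstream depends on it
beyond consistency.

## Stacked ensemble

Base learners: RBF-kernel SVM (with sigmoid/Platt calibration, 3-fold, to
produce class probabilities), k-nearest neighbours, logistic regression,
random forest, decision tree, and XGBoost.  Named combinations:
SM1 = {KNN, LR, DT, SVM}, SM2 = {KNN, LR, DT, XGB}, SM3 = {KNN, LR, DT, RF},
SM4 = {SVM, XGB, RF}, SM5 = all six.  SM1 is the default predictor.

Meta-features are **out-of-fold** positive-class probabilities: a
stratified `n_meta_folds`-fold split (default 5) of the training data; each
base learner is trained on the complement of a fold and scores that fold.
A sample's meta-features therefore never come from a learner that saw its
fold, which is the standard leakage-free stacking construction (the
alternative — resubstitution probabilities — would let memorizing learners
leak labels into the meta-stage).  Only the positive-class probability is
kept (one column per learner; the negative-class column is redundant for a
binary task).

The meta-classifier is a gradient-boosted decision-tree ensemble
(100 trees, depth 3, learning rate 0.1 by default; fully overridable via
`StackConfig.meta`).  After the meta-fit, each base learner is refit on the
full training set; prediction runs input → refit base probabilities → meta
probability.  Hard labels use `probability >= threshold` (default 0.5).

Optional standardization (train-partition mean/variance) is applied inside
the SVM/KNN/LR pipelines only; tree learners consume raw features.  Grid
search for base hyperparameters maximizes mean stratified-CV accuracy,
enumerating the grid in insertion order with first-candidate tie-breaking;
tuning happens once on the full training partition before stacking (not
inside every jackknife iteration — tractable, at the cost of a small,
documented optimistic bias).  All randomized components (fold shuffling,
tree learners, calibration) derive from the single config seed; identical
config and data give a byte-identical serialized model.

## Evaluation

Counts are tallied with positive = DBP = 1.  OA, SN, SP follow the usual
confusion-table ratios; SN/SP with an empty denominator are reported as
NaN, never silently zero.  MCC uses the standard square-root denominator,
defined as 0 when any factor is zero; a non-square-root variant
(`mcc_linear`) is exposed for comparison but is not the default, since
MCC values on the natural [-1, 1] scale require the root.  ROC is a
threshold sweep over distinct scores (ties grouped) and AUC its trapezoidal
area, equal to the tie-corrected Mann–Whitney probability.

Cross-validated protocols pool the held-out predictions: the jackknife
trains one full stack per left-out protein (meta folds re-drawn from the
config seed each time) and computes metrics once over the `n` pooled
probabilities; stratified k-fold is the cheaper surrogate, and `k = n`
reduces to the jackknife by construction (leave-one-out fold order).  AUC
on CV is computed from the pooled probabilities (one curve), not averaged
per-fold curves.  The CLI falls back from jackknife to 10-fold when
`n > 300` unless forced, because jackknife stacking is `O(n)` full
re-trainings.  The independent test is a single pass of a trained model
over a disjoint labeled set; overlapping ids (checked against the model's
training fingerprint) raise a warning.

Percentages are printed to 2 decimals and MCC/AUC to 4.

## Synthetic data

The generator emulates what HHblits would produce, at the level the feature
map sees: per-protein `L x 20` emission profiles with class-dependent
biases.  Hierarchy: a class mean (shared background composition tilted in
log space by a fixed mean-zero direction of amplitude
`0.1 * separation`, `+` for DBPs and `-` for non-DBPs); a protein-level
Dirichlet draw around the class mean (concentration 100); and per-row
Dirichlet draws (concentration 50) around a blend of the protein profile
and the previous row (blend 0.3), so adjacent rows are correlated and the
TPC features carry class signal beyond composition.  Probabilities are
quantized to scores `round(-1000 * log2 p)`; values below `2^-20` become
`*`, mirroring HHsuite's convention, with additional `*` dropout at
`star_rate` (default 0.02).  Lengths are uniform on (50, 300) by default,
respecting the benchmark convention of excluding proteins under 50
residues.

Calibration of the defaults, chosen from a signal/noise argument before
any end-to-end measurement: the class shift per AAC feature is about
`0.01 * separation` while the protein-level (non-averaging) noise sd is
about `0.021`, giving a combined between-class z of roughly
`2.1 * separation` over the 20 AAC features.  `separation = 1` (default)
is therefore a moderate problem (single-learner CV accuracy ~0.75–0.85),
`3` is nearly separable (SVM ≥ 0.9), and `0` makes the classes
exchangeable.

What the generator does **not** emulate: phylogenetic correlation
structure of real alignments, HHblits search artifacts, position-specific
conservation patterns, or realistic amino-acid backgrounds.  Passing tests
on synthetic data therefore validate the pipeline's mechanics and the
qualitative behaviour of its statistics, not the published benchmark
accuracies, which require HHblits profiles of the real benchmark proteins.

## Numerical and degenerate-input choices

- `*` scores are exactly 0 after normalization; all-`*` rows are legal.
- TPC requires `L >= 2` and raises otherwise (the <50-residue exclusion
  makes this unreachable on benchmark-style data).
- Zero-denominator TPC rows are all-zero (see above).
- Stratified folds require each class to have at least as many members as
  folds; violations raise immediately with the class count.
- Meta-features that come out constant are permitted but flagged in the
  model's training fingerprint.
- Model files embed a format version; mismatches and truncated files raise.

## Known limitations

- At desk scale (around 100 training proteins) the GBDT meta-classifier
  must learn from out-of-fold probabilities of models trained on ~70
  samples, and the base columns are dominated by the SVM; the stack then
  ties rather than beats the best single base learner.  The advantage of
  stacking over the best base emerges with larger training sets.  This is a
  property of leakage-free stacking at small `n` (scikit-learn's
  `StackingClassifier` with the same configuration behaves identically),
  not of this implementation.
- Jackknife evaluation retrains the full stack `n` times; use k-fold for
  large datasets.
- Only binary classification is supported; probabilities are not
  post-calibrated at the stack level.
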