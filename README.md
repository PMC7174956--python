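# hmmstack

Sequence-based prediction of DNA-binding proteins (DBPs) from profile-HMM
evolutionary features with a two-stage stacked ensemble.

DBPs drive transcription, replication, recombination and repair, and
identifying them experimentally is slow.  `hmmstack` implements a purely
sequence-based predictor: each protein is represented by the match-state
emissions of its profile hidden Markov model (an HHsuite `.hhm` file, as
produced by HHblits), encoded into a fixed-length feature vector, and
classified by a stacked ensemble of standard learners.

## Method

**Features.** The profile's `L x 20` match-emission block stores integer
scores `x = -1000 * log2(p)` (`*` for negligible probability).  Scores are
normalized to probabilities

```
f(x) = 0        if x = *
f(x) = 2^(-x/1000)   otherwise
```

giving a matrix `h` with `h[i][j] ∈ [0, 1]`.  Two summaries are fused:

- **AAC** (amino-acid composition, 20 features):
  `x_j = (1/L) Σ_i h[i][j]` — the mean emission probability of amino acid
  `j` over all match states.
- **TPC** (transition probability composition, 400 features):
  `y[i][j] = Σ_k h[k][i] · h[k+1][j] / Σ_j' Σ_k h[k][i] · h[k+1][j']` —
  the row-normalized co-emission of amino acid `i` at one position and `j`
  at the next, capturing first-order sequence order.

Their concatenation is the 420-dimensional AATP vector.

**Classifier.** Stage 1 trains base classifiers (KNN, logistic regression,
decision tree, RBF-kernel SVM, random forest, XGBoost in any of the named
combinations SM1–SM5) and produces leakage-free *out-of-fold* positive-class
probabilities via stratified 5-fold splitting.  Stage 2 fits a
gradient-boosted decision tree (GBDT) meta-classifier on those
probabilities.  SM1 (KNN + LR + DT + SVM-RBF) is the default predictor.

**Evaluation.** Overall accuracy, sensitivity, specificity, Matthews
correlation coefficient and ROC/AUC over pooled predictions, under the
jackknife (leave-one-out), stratified k-fold CV, or an independent test.

A synthetic-data module generates realistic two-class `.hhm` datasets with
controllable class separation, so the entire pipeline runs and is tested
without any external profile database.

## Worked example

```python
import hmmstack as hs

work = "/tmp/demo"
ds = hs.generate_dataset(
    hs.SimulationConfig(n_pos=15, n_neg=15, separation=2.0, seed=3), work)
fm = hs.batch_encode(ds)                      # 30 x 420 feature matrix
config = hs.StackConfig("SM1", seed=3)
print(hs.kfold_evaluate(config, fm, k=10, seed=3).summary())
print(hs.jackknife_evaluate(config, fm).summary())
```

prints

```
protocol=kfold(k=10, seed=3)  OA=96.67%  SN=100.00%  SP=93.33%  MCC=0.9354  AUC=0.9444
protocol=jackknife  OA=96.67%  SN=100.00%  SP=93.33%  MCC=0.9354  AUC=0.9333
```

OA is the percentage of correct calls over the 30 pooled held-out
predictions; SN and SP split that by true class (DBP / non-DBP); MCC is the
correlation between predicted and true labels; AUC is the probability that
a random DBP outscores a random non-DBP.  The `examples/` directory holds
one narrative script per capability (parsing/encoding, simulation,
train/predict, cross-validation), and the `hmmstack` CLI exposes the same
pipeline (`simulate`, `extract-features`, `train`, `predict`, `evaluate`,
`independent-test`) with a JSON run manifest next to every output.

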