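"""Train the SM1 stacked ensemble and score a disjoint test set.

SM1 stacks KNN, logistic regression, a decision tree and an RBF-kernel SVM;
their out-of-fold positive-class probabilities train a gradient-boosted
decision-tree meta-classifier.
"""

import tempfile
from pathlib import Path

import hmmstack as hs

work = Path(tempfile.mkdtemp(prefix="hmmstack_example_"))
train_ds = hs.generate_dataset(
    hs.SimulationConfig(n_pos=30, n_neg=30, separation=1.5, seed=1),
    work / "train")
test_ds = hs.generate_dataset(
    hs.SimulationConfig(n_pos=15, n_neg=15, separation=1.5, seed=2),
    work / "test", id_prefix="held_")

fm_train = hs.batch_encode(train_ds)
fm_test = hs.batch_encode(test_ds)

config = hs.StackConfig("SM1", seed=0)
model = hs.train_stacked(config, fm_train)
print("base learners:", [name for name, _ in model.fitted_base])
print("trained on:", model.training_fingerprint["n"], "proteins")

proba = hs.predict_proba(model, fm_test)
print("first five predicted P(DNA-binding):", [round(p, 3) for p in proba[:5]])

report = hs.independent_test(model, fm_test)
print("independent test:", report.summary())
# OA/SN/SP are percentages of correct, correctly-positive and
# correctly-negative calls; MCC in [-1, 1]; AUC is ranking quality.
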