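"""Cross-validated evaluation: stratified 10-fold and the full jackknife.

The jackknife (leave-one-out) scores every protein with a stack trained on
all the others; 10-fold is its cheaper surrogate.  Metrics are pooled over
the held-out predictions, giving one confusion table and one ROC curve.
"""

import tempfile

import hmmstack as hs

work = tempfile.mkdtemp(prefix="hmmstack_example_")
ds = hs.generate_dataset(
    hs.SimulationConfig(n_pos=15, n_neg=15, separation=2.0, seed=3), work)
fm = hs.batch_encode(ds)
config = hs.StackConfig("SM1", seed=3)

kfold = hs.kfold_evaluate(config, fm, k=10, seed=3)
print("10-fold: ", kfold.summary())

jack = hs.jackknife_evaluate(config, fm)
print("jackknife:", jack.summary())
c = jack.counts
print(f"jackknife confusion table: TP={c.TP} FP={c.FP} TN={c.TN} FN={c.FN}")
print("ROC endpoints:", jack.roc[0], "->", jack.roc[-1])
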