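"""Train the multi-modal classifier end-to-end and evaluate it.

A compact model (same architecture as the full-size configuration, smaller
layer sizes) is trained on the default synthetic dataset and scored on a
held-out stratified test split with the standard multiclass metric suite.
"""

import warnings

import ncfuse as nf

warnings.filterwarnings("ignore")

ds = nf.simulate_dataset(nf.SynthConfig(seed=7))
train_idx, test_idx = nf.stratified_split(ds, test_fraction=0.2, seed=0)

model_cfg = nf.ModelConfig.from_dataset(ds)
train_cfg = nf.desk_train_config(seed=0, epochs=16)
model, history = nf.train(ds.subset(train_idx), model_cfg, train_cfg)
print(f"trained {len(train_idx)} samples, {train_cfg.epochs} epochs; "
      f"loss {history[0]:.3f} -> {history[-1]:.3f}")

report = nf.evaluate(model, ds.subset(test_idx))
print(f"test accuracy {report.accuracy:.3f}  MCC {report.mcc:.3f}  "
      f"macro-F1 {report.macro_f1:.3f}  (n={report.n})")
print("confusion matrix (rows = true class, cols = predicted):")
for name, row in zip(ds.class_names, report.confusion):
    print(f"  {name:10s} {row.tolist()}")
# Accuracy near 1.0 means the fused representation recovered the planted
# class signal; the confusion matrix shows where residual mistakes fall.
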