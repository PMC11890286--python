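"""Interpretability: which modality does the model rely on, per class?

Here the generator plants class signal only in expression; after training,
each class's mean attention should concentrate on the expression column.
The exported table is the data behind a class-grouped attention heatmap.
"""

import warnings

import ncfuse as nf

warnings.filterwarnings("ignore")

cfg = nf.SynthConfig(seed=7, signal_strengths={"sequence": 0.0,
                                               "structure": 0.0,
                                               "expression": 0.9})
ds = nf.simulate_dataset(cfg)
train_idx, test_idx = nf.stratified_split(ds, 0.2, seed=0)
model, _ = nf.train(ds.subset(train_idx), nf.ModelConfig.from_dataset(ds),
                    nf.desk_train_config(seed=0, epochs=16))

table = nf.export_attention(model, ds.subset(test_idx))
print("per-class mean attention (rows sum to ~1 over present modalities):")
print(table.class_summary[[f"{m}_mean" for m in ds.modality_names]]
      .round(3).to_string())

ranking = nf.class_annotation(table)
for cls, groups in ranking.items():
    chain = " > ".join(" = ".join(f"{m} ({mu:.2f})" for m, mu, _ in g)
                       for g in groups)
    print(f"  {cls}: {chain}")
# Expression tops every class: the attention coefficients recover which
# modality carried the (here: planted) class-defining signal.
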