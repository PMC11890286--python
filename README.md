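# ncfuse

Attention-based multi-modal classification of non-coding RNAs.

Non-coding RNAs (ncRNAs) fall into functional classes — miRNA, snoRNA,
snRNA, lncRNA, tRNA, rRNA and others — and assigning an unannotated
transcript to a class is a routine step in characterising it. Different
classes are recognisable through different *modalities*: some carry
conserved sequence motifs, some a distinctive secondary structure, some a
tissue-specific expression pattern. Most classifiers use one modality, at
most two, and none of their scores explain *which* view of the molecule
drove a prediction.

`ncfuse` implements an interpretable intermediate-integration classifier
for up to three modalities:

- **sequence** — one-hot nucleotide matrix through stacked 1-D
  convolutional blocks (conv → leaky ReLU → batch norm → max pool →
  dropout) and fully connected blocks;
- **secondary structure** — the base-pairing graph (nodes = nucleotides,
  typed edges = backbone bonds and base pairs) through SAGE-style graph
  convolutions with per-edge-type aggregation and a Set2Set readout;
- **expression** — the per-condition expression vector through an MLP.

Each encoder yields a vector x&#775;<sub>m</sub> ∈ R<sup>D_m</sup>. These are
projected into a shared space, x&#776;<sub>m</sub> = W<sub>m</sub>x&#775;<sub>m</sub> + b<sub>m</sub> ∈ R<sup>D</sup>,
mapped column-wise to query/key/value matrices Q, K, V ∈ R<sup>D×M</sup>, and
compared through the scaled interaction matrix

&nbsp;&nbsp;&nbsp;&nbsp;C<sub>nm</sub> = Q<sub>m</sub><sup>T</sup> K<sub>n</sub> / √D,

whose diagonal holds self-attention and off-diagonal cross-modal terms. A
perceptron P<sub>A</sub>(C) = W<sub>A</sub>C + b<sub>A</sub> with W<sub>A</sub> ∈ R<sup>1×M</sup>
contracts C to one score per modality and a softmax gives the attention
coefficients A = softmax(P<sub>A</sub>(C)). The fused representation is the
attention-weighted concatenation x<sub>A</sub> = [A₁V₁, …, A_M V_M], classified
by fully connected ReLU layers with a softmax output, trained end-to-end
with cross-entropy.

**Missing modalities** (e.g. transcripts absent from the expression matrix)
are handled by masking, not imputation: a missing modality enters the
encoders as a zero placeholder, its pre-softmax attention score is driven
to −∞ so its coefficient is exactly zero, and the remaining coefficients
renormalise over the present modalities. The per-sample attention vector A
doubles as the interpretability output: aggregated per class, it reports
which modality characterises each class.

A synthetic-data generator emulates all four input files with
class-specific signal planted per modality (sequence motif, hairpin stem
length, expression profile) and an exact fraction of transcripts missing
from the expression matrix, so the whole pipeline runs without downloads.

The neural layers (autodiff, Conv1d, batch norm, LSTM-based Set2Set,
typed graph convolution, Adam) are implemented on numpy inside
`ncfuse.nn`.

## Worked example

```python
import ncfuse as nf

ds = nf.simulate_dataset(nf.SynthConfig(seed=7))          # 3 classes x 200
tr, te = nf.stratified_split(ds, test_fraction=0.2, seed=0)
model, history = nf.train(ds.subset(tr), nf.ModelConfig.from_dataset(ds),
                          nf.desk_train_config(seed=0, epochs=16))
print(nf.evaluate(model, ds.subset(te)).accuracy)
```

Running `python examples/02_train_and_evaluate.py` (the same computation)
prints:

```
trained 480 samples, 16 epochs; loss 1.040 -> 0.032
test accuracy 0.933  MCC 0.903  macro-F1 0.933  (n=120)
```

i.e. the fused model recovers the planted class structure almost
completely from 16 epochs on one CPU. `examples/03_attention_annotation.py`
plants signal only in expression and shows the interpretability output —
per-class mean attention concentrating on the informative modality:

```
            sequence_mean  structure_mean  expression_mean
mir-like            0.217           0.008            0.775
sno-like            0.236           0.014            0.750
snr-like            0.229           0.021            0.750
```

`examples/04_missing_data_and_ablation.py` runs the modality-ablation and
missing-data studies; `examples/01_simulate_and_inspect.py` shows the
generated file formats.

## Command line

Every step is also a subcommand (`ncfuse simulate | train | predict |
evaluate | ablate | explain`); flags override the optional YAML config, a
run manifest with input checksums is written before training, and
machine-readable outputs (metrics, confusion matrix, predictions,
attention tables) land in `--out` as TSV.

```sh
ncfuse simulate --out data --seed 7
ncfuse train --fasta data/sequences.fasta --structures data/structures.db \
             --expression data/expression.tsv --labels data/labels.tsv \
             --out run --seed 0
ncfuse explain --model run/model.npz --fasta data/sequences.fasta \
               --structures data/structures.db --expression data/expression.tsv \
               --labels data/labels.tsv --out explained --heatmap
```

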