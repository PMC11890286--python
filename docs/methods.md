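# Methods

## Model

A sample x is described by M modalities x = [x₁, …, x_M] (here M ≤ 3:
sequence, secondary structure, expression). Each modality is encoded
independently, x&#775;_m = Enc_m(x_m) ∈ R^{D_m}; the encodings are fused by a
cross-modal attention layer; the fused vector is classified. Training is
end-to-end with multiclass cross-entropy.

### Encoders

**Sequence.** The nucleotide string is one-hot encoded as a 4 × max_len
matrix (rows A, C, G, U; zero right-padding; degenerate IUPAC letters give
an all-zero column — "no information" rather than an arbitrary assignment).
Convolutional blocks apply a 1-D convolution ('same' zero padding), leaky
ReLU (slope 0.01), batch normalisation, width-2/stride-2 max pooling, and
dropout; the flattened output passes through fully connected blocks with
the same activation, normalisation and dropout. The full-size default is
five blocks of 256 channels, kernel 10, dropout 0.2, FC sizes [128, 64],
max_len 1200 nt (sequences beyond max_len are truncated with a warning).
The configuration requires max_len ≥ 2^(number of blocks) and rejects
anything smaller at build time.

**Structure.** The dot-bracket string becomes a graph: one node per
nucleotide (5-category one-hot: A/C/G/U/other; no positional feature),
backbone edges between adjacent positions, pair edges from stack-matching
round brackets. Non-round brackets (pseudoknot annotations) are treated as
unpaired with a warning — the upstream structure predictors this tool
expects are pseudoknot-free. Each of the (default five) graph blocks is a
SAGE-style convolution with leaky ReLU, batch norm and dropout. SAGE
aggregation does not natively consume edge attributes, so edge typing is
realised as one mean-aggregation per edge type with its own weight matrix,

  h_i' = W_root x_i + W_bb · mean_{j∈N_bb(i)} x_j + W_pair · mean_{j∈N_pair(i)} x_j + b,

which stays within the SAGE family while distinguishing backbone bonds
from base pairs. Node sets are pooled with Set2Set (3 processing steps, an
LSTM querying the node set by content-based attention); Set2Set doubles
the node dimension, so D_struct = 2 × conv_size. A minibatch of graphs is
processed as one disjoint union with sparse adjacency and a per-graph
segment softmax in the readout; this is an implementation detail with no
effect on semantics (batched and one-at-a-time encodings agree to float32
tolerance, and the readout is invariant to node relabelling).

**Expression.** The per-condition vector passes through fully connected
blocks (linear → ReLU → batch norm → dropout); full-size default
[2048, 512, 64] with dropout 0.4. Normalisation of expression values is
upstream: the reader accepts values as given.

### Attention integration

Encodings are projected into a shared space of dimension D (default 64,
matching the encoders' final sizes so the projections start
well-conditioned): x&#776;_m = W_m x&#775;_m + b_m. The column matrix
x&#776; ∈ R^{D×M} is mapped by three affine maps to Q, K, V ∈ R^{D×M}, and

  C_nm = Q_mᵀ K_n / √D

forms the interaction matrix (diagonal = self-attention, off-diagonal =
cross-modal attention). A perceptron W_A C + b_A (W_A ∈ R^{1×M}) contracts
C along its key index to one score per query modality; no nonlinearity is
applied before the softmax (the defining equations show an affine map
only). The softmax of the scores gives coefficients A, and the fused
representation is x_A = [A₁V₁, …, A_M V_M] ∈ R^{M·D}.

One orientation note: Q and K columns are modality vectors (the natural
reading that makes C ∈ R^{M×M} dimensionally consistent); any consistent
alternative orientation changes only parameter bookkeeping, not capacity.
The scaling constant is the shared dimension D.

### Missing modalities

A missing modality contributes an all-zero *encoded* vector (the encoder
never sees raw data for it), so its projected column is the bias b_m — a
learned constant. Masking acts on the pre-softmax scores: masked entries
are driven to −∞ (implemented as a −10⁹ additive penalty, which underflows
to an exact zero coefficient after max-subtracted softmax), so A is a
proper distribution over the present modalities. Belt-and-braces, the
masked coefficients and fused blocks are multiplied by the mask again, so
zeros are exact by construction. Consequences, both tested: Σ_m A_m = 1
over present modalities, and no perturbation of a missing modality's raw
data can change any output. No imputation is performed anywhere.

### Classification head and loss

Hidden affine+ReLU layers (default [64, 32] — deliberately weaker than the
encoders, since the representation is the point) and a final affine layer;
softmax is folded into a log-sum-exp cross-entropy on logits for numerical
stability. Argmax ties break to the lowest class index. Class name → index
mapping is lexicographic, for determinism across runs.

## Training

Adam (lr 1e-3), batch size 32, up to 100 epochs with early stopping on a
stratified validation split (patience 10) are the full-size defaults; all
are config-exposed. Every source of randomness — initialisation, batch
order, dropout, splits — derives from the single seed in `TrainConfig`.
Batches may mix samples with different masks.

Desk scale: the test suite, examples and acceptance script use
`ModelConfig.compact()` (3 conv blocks × 32 channels, 2 graph blocks × 32,
expression MLP [64, 64], fusion D = 32, head [32]) and
`desk_train_config()` (16 epochs, batch 64, lr 2e-3, no early-stopping
split), which trains a 600-sample three-modality dataset in tens of
seconds on one CPU. These are the package's chosen problem sizes for its
bundled synthetic data; the full-size defaults remain available.

### Evaluation and protocols

Metrics: accuracy, multiclass Matthews correlation, and macro-averaged
precision/recall/F1, all derived from the confusion matrix over the full
class list (a class absent from both truth and prediction contributes 0
with a warning). Cross-validation is stratified k-fold: every sample
validates exactly once and per-fold class counts are within one sample of
proportionality; a class smaller than k is an error naming the class.

The ablation harness trains one model per modality subset with identical
seed and split. Because single-modality models cannot score samples
lacking that modality, the shared test split is drawn from complete
samples only, so all subsets are scored on identical samples; training
uses every sample usable under its subset. The missing-data study shares
this design: one complete-sample test split, one model trained on all
remaining samples (masking), one on complete samples only.

## Synthetic data

The generator emulates a multi-cohort ncRNA dataset as four text files
(FASTA, dot-bracket, expression TSV, labels TSV) plus a manifest recording
every planted signal. Per class: a short sequence motif planted at a
random unpaired position with probability `signal_strengths['sequence']`
(skipped, and recorded as such, if no unpaired run fits — paired positions
always stay complementary); one stem-loop whose stem length is
class-specific with probability `signal_strengths['structure']` and
random otherwise; expression drawn lognormally (σ = 0.5) around a
class-specific mean profile interpolated toward the global mean as the
signal strength decreases. Structures are emitted by a stem-loop grammar
directly (no external folding tool), and paired positions are forced
complementary (A–U, G–C) so sequence and structure are mutually
consistent. Exactly round(missing_expr_frac × n) transcripts, chosen
uniformly, are omitted from the expression file — missingness is exact,
not expected, and is signalled by row absence (an all-zero row is *not*
missing).

Defaults: 3 classes × 200 samples, lengths 40–120 nt, 10 conditions,
missing_expr_frac 0.23, signal strengths 0.9 per modality. The length
range and condition count are desk-scale choices — long enough for
distinct stems (5/10/16 nt) and motifs (8 nt) to fit, short enough that a
CNN trains in seconds; the missingness fraction mirrors the scale of
missing expression seen in real merged cohorts. What the generator does
*not* emulate: realistic family sequence composition, cohort batch
effects, pseudoknots, class imbalance. Passing tests therefore demonstrate
that the architecture recovers modality-specific class signal and honours
the masking contract — not field performance on real data.

## Numerical choices

- float32 forward/backward (standard DL practice); the functional fusion
  API is float64 and is the reference semantics.
- Softmax and cross-entropy use max-subtraction / log-sum-exp.
- Batch-norm eval mode uses running statistics (momentum 0.1, ε 1e-5);
  train mode normalises by batch statistics.
- cross_entropy on probabilities clamps a zero true-class probability at
  1e-12 with a warning.
- Kaiming-uniform initialisation; leaky-ReLU slope 0.01.
- The `worked_example()` fixture (12 samples, frozen seed) is
  byte-identical across runs and guarded by a checksum test.

## Limitations

- Graph batching uses one dense-ish sparse matmul per edge type per block;
  very long RNAs (thousands of nt) are supported but not fast.
- The attention vector has one coefficient per modality — it explains
  which *source* mattered, not which positions within a sequence.
- Batch statistics in train mode couple samples within a batch, so
  training losses are not bit-reproducible across different batch sizes
  (eval mode is deterministic).
- Pseudoknots and non-canonical pairs are not modelled.
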