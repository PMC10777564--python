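# gkmgraph

Essential-gene prediction from DNA sequence alone, by encoding each gene as a
**gapped k-mer sequence feature graph** and classifying the graph with a
**graph-convolutional neural network**.

Essential genes — genes whose loss is lethal to the organism — are the
positive class in a binary sequence-classification task. Wet-lab essentiality
screens are expensive, so sequence-based predictors matter; this package
implements a pipeline that needs nothing but the nucleotide sequence.

## The model

**Encoding.** A sequence of length *L* is slid over with a window of size
*k*, giving its *L − k + 1* contiguous k-mers. With a gap distance *d* ≥ 2,
additional *gapped* matches are collected: k informative bases where one
internal junction skips *d − 1* positions (a gapped 3-mer with *d* = 3 is
written `GT**A`). Gapped matches absorb small sequence variation into the
same k-mer counts. The sequence becomes a graph *G = (n, e)*: one node per
k-mer with feature = occurrence frequency, and an undirected edge between
k-mers occurring as consecutive windows, weighted by co-occurrence count.

**Classifier.** Over the fixed 4^k-node universe the network stacks four
graph convolutions

```
Z_i = Σ_{j∈N(i)}  a_ij / √(d_i d_j) · h_j · W ,      H_i = ReLU(Z_i)
```

(`a_ij` = edge weight in the default weighted mode, 1 in the literal
unweighted mode), reads the node representations out in lexicographic k-mer
order as a 1-D signal, applies three 1-D convolutional layers, and classifies
with

```
ŷ = softmax( ReLU(W₁·x + b₁) · W₂ + b₂ )
```

trained by mini-batch SGD on class-weighted binary cross-entropy. Evaluation
reports SN, SP, ACC, PRE, F1, MCC and rank-based AUC
(`AUC = (Σ_{i∈pos} rank_i − n_pos(n_pos+1)/2) / (n_pos · n_neg)`, average
ranks on ties). All forward/backward passes are explicit NumPy with analytic
gradients, verified against finite differences in the test suite.

A seeded Markov-chain generator provides two-class synthetic benchmarks whose
classes share mono- and dinucleotide statistics but differ in trinucleotide
composition — so the planted signal is only visible at k = 3, mirroring the
intended use of the encoder grid.

## Worked example

```python
from gkmgraph import (EncoderConfig, GeneratorConfig, ModelConfig, SplitSpec,
                      TrainConfig, generate_dataset, split_dataset,
                      train_model, predict)
from gkmgraph.evaluation import evaluate_predictions

ds = generate_dataset(GeneratorConfig(n_per_class=100, length=300, seed=7))
train, val, test = split_dataset(ds, SplitSpec(seed=7))   # stratified 8:1:1

enc = EncoderConfig(k=3, d=3)
params, log = train_model(train, val, enc, ModelConfig(seed=7),
                          TrainConfig(epochs=60, seed=7))
scores, hard = predict(test, enc, params)
panel = evaluate_predictions(test.labels, scores, hard)
print(f"final train loss {log['train_loss'].iloc[-1]:.4f}, "
      f"val ACC {log['val_acc'].iloc[-1]:.3f}")
for name, v in panel.as_dict().items():
    print(f"{name:4s} {v:.4f}")
```

prints

```
final train loss 0.0038, val ACC 1.000
SN   1.0000
SP   0.9000
ACC  0.9500
PRE  0.9091
F1   0.9524
MCC  0.9045
AUC  1.0000
```

i.e. on a 20-record held-out split of a strongly planted trinucleotide
signal, every essential gene is recovered (SN = 1.0), one non-essential gene
is misclassified (SP = 0.9), and the score ranking is perfect (AUC = 1.0).

The same pipeline is available from the shell:

```sh
gkmgraph simulate --n-per-class 100 --seed 7 --out run/data
gkmgraph crossval --fasta run/data/sequences.fasta --labels run/data/labels.tsv \
                  --k 3 --d 3 --folds 10 --out run/cv
gkmgraph grid     --fasta run/data/sequences.fasta --labels run/data/labels.tsv \
                  --grid "2,2;2,3;3,2;3,3" --out run/grid
gkmgraph ablate   --fasta run/data/sequences.fasta --labels run/data/labels.tsv \
                  --depths 1,2,3,4,5 --out run/ablate
```

Every command writes a `manifest.json` (config echo + seed + format version)
from which the run can be reproduced exactly.

## Layout

- `gkmgraph.sequence_io` — FASTA/TSV reading, validation, stratified
  splitting and k-fold construction
- `gkmgraph.encoding` — contiguous and gapped k-mer extraction, graph
  construction, TSV serialization
- `gkmgraph.model` — the network, loss, analytic gradients, SGD training,
  prediction, checkpointing
- `gkmgraph.evaluation` — metric panel, cross-validation, encoder-grid and
  depth-ablation drivers
- `gkmgraph.simulate` — seeded Markov-chain benchmark generator
- `gkmgraph.cli` — the `gkmgraph` command

See `docs/methods.md` for modeling assumptions, parameter defaults and known
limitations.
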