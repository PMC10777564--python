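# Methods

## Sequence feature graphs

A DNA sequence of length *L* over {A,C,G,T,N} is encoded as a graph over the
k-mer universe.

**Contiguous windows.** Sliding a window of *k* bases yields the
*L − k + 1* contiguous k-mers in order (zero windows when *L < k*). Windows
containing N are emitted but excluded from all counting; an adjacency pair is
dropped if either member is invalid.

**Gapped matches.** The gap distance *d* is the positional distance between
the two informative bases flanking the gap, so *d − 1* positions are skipped
and *d = 1* degenerates to the contiguous case. For *d ≥ 2*, every internal
junction *j* (1 ≤ j ≤ k−1) is enumerated: *j* contiguous informative bases, a
gap of *d − 1* skipped positions, then the remaining *k − j* contiguous
bases; each match spans *k + d − 1* positions, giving
max(0, L − (k + d − 1) + 1) matches per junction on N-free sequence. A gapped
match is collapsed onto the node of its informative bases (`GT**A` counts
toward node `GTA`): the gap augments the robustness of the counts, it does
not enlarge the node set.

**Graph.** Nodes are the full 4^k universe in lexicographic order by default
(absent k-mers get zero features and stay isolated), which gives every graph
an identical node set and makes the downstream fixed-shape readout well
defined; an "observed" universe mode exists for inspection but is rejected by
the readout. Node features pool contiguous and gapped counts; in the default
relative mode they are divided by the number of valid counted windows and
hence sum to 1. Edges connect consecutively occurring contiguous windows,
undirected (the symmetric degree normalization of the aggregation step
presumes an undirected graph; gapped matches have no well-defined successor),
with accumulated integer weights and self-loops allowed. Coordinates are
0-based half-open internally.

## Network

Input node features are scalars (the frequencies), so H⁰ is (4^k × 1). Each
graph convolution computes Z = Â H W followed by ReLU, with
Â = D^(−1/2) A D^(−1/2); isolated nodes yield zero rows, and no self term is
added unless a self-loop edge exists (the aggregation sums over neighbors
only — a deliberate, testable divergence from the common add-self-loop
practice). In the default mode A holds the edge weights and D the weighted
degrees, so the co-occurrence counts that the encoder computes actually
influence aggregation; `use_edge_weights=False` restores the literal
unit-coefficient form. Both modes are tested against a dense oracle.

The final node representations are read out in lexicographic k-mer order as a
(channels × 4^k) signal, passed through three length-preserving 1-D
convolutions (stride 1, odd kernel, ReLU), flattened, and classified by
softmax(ReLU(W₁x + b₁)W₂ + b₂). The positive-class probability is the score;
hard labels use argmax with ties (score exactly 0.5) broken toward the
negative class, the conservative choice for the essential-gene call.

Defaults (all configurable): 4 GCN layers of widths [16, 32, 32, 16]
(shallower stacks take a prefix, deeper ones repeat the last width), conv
channels [16, 32, 16] with kernel size 3, fully connected width 64.

## Training

Plain mini-batch SGD (learning rate 0.01, batch 32, epochs 100) on binary
cross-entropy with probabilities clipped to [1e-12, 1 − 1e-12]. Class
weighting defaults to inverse class frequency normalized so balanced classes
recover unit weights, w_c = N / (2 N_c), countering the class imbalance
typical of essentiality datasets; it can be disabled or set explicitly.
Early stopping (monitoring validation loss with a stated patience, restoring
the best parameters) is available but off by default so the epoch count is
exact. All parameters initialize from a seeded generator with symmetric
uniform draws of bound √(6 / fan_in); that He-style gain keeps activation
variance roughly constant through the ReLU stacks. Input node features are
multiplied by the node count 4^k on entry (`input_scale`), so a uniform
relative-frequency profile has unit features; without this the ~4^(−k)-scale
inputs drive all activations toward zero and SGD stalls at the uniform
predictor. Identical seeds and data give bitwise-identical trajectories.

Backpropagation is hand-derived and exact: softmax cross-entropy to logits,
dense linear algebra through the head and the im2col convolutions, and
Â-symmetric chaining through the graph convolutions. The test suite checks
every parameter coordinate of the full-model gradient against central finite
differences (relative error < 1e-4) on a micro-batch. The comparison jitters
parameters first: biases initialize to exactly zero while absent k-mers
produce exactly-zero activations, which puts pre-activations exactly on the
ReLU kink where a central difference averages two one-sided slopes and no
comparison against a (sub)gradient is meaningful.

## Evaluation

SN, SP, ACC, PRE, F1 and MCC follow the standard confusion-count formulas;
AUC uses the Mann–Whitney rank formula with average ranks on ties (equal to
the correctly-ordered-pair fraction with ties counted ½; verified against
both a pair-counting oracle and scikit-learn). Zero-denominator ratios are
reported as 0 with a logged warning; AUC over a single class is reported as
0.5 with a warning — explicit flags rather than silent NaN propagation.

Splitting is stratified 8:1:1 with a largest-remainder rounding rule per
class and an explicit seed (ties in the fractional parts resolve in
train/validation/test order). Cross-validation uses stratified k-fold (k = 10
by default) with the held-out part of each fold doubling as the validation
set for the training log. The encoder-grid driver ranks (k, d) pairs by mean
cross-validated ACC with ties broken by higher AUC then smaller k; the depth
sweep reports one panel per GCN depth without automatic selection.

## Synthetic benchmark

Both classes are order-2 Markov chains over {A,C,G,T}. The negative class is
the uniform base model; the positive class mixes in a doubly centered random
perturbation: every transition row still sums to 1, and the perturbation sums
to zero over the oldest context base, so the uniform distribution over
dinucleotide contexts remains stationary for both classes. Expected mono- and
dinucleotide frequencies are therefore matched exactly, while trinucleotide
frequencies differ by up to ±0.2·s per transition entry (s = signal
strength). This plants a signal that a k = 3 encoder can see but a k = 2
encoder cannot, which is exactly the property the grid experiment needs. The
generator defaults — 200 sequences per class, length 300, signal strength
0.8, seeded — are the package's standard study conditions; an imbalance
ratio exercises the class-weighting path. `empirical_kmer_divergence`
(total-variation distance between pooled per-class k-mer frequencies) is the
diagnostic for how much signal a draw actually contains.

What the generator does **not** emulate: codon or reading-frame structure,
species-specific GC content, homology between records, or the redundancy
filtering applied to curated essentiality datasets. Passing the synthetic
benchmarks therefore demonstrates that the pipeline recovers compositional
k-mer signal of the planted kind, not that it attains any particular accuracy
on real genomes.

## Problem sizes and numerical choices

The experiment drivers in the tests and the reproduction script run at desk
scale, chosen as the smallest sizes at which the statistical claims are
clean: signal-recovery runs train on the 8:1:1 split of the 400-sequence
default dataset for the full 100 epochs (held-out n = 40, so the chance band
0.5 ± 3·0.5/√40 ≈ [0.26, 0.74] cleanly separates from the ≥ 0.85 recovery
criterion); the grid and depth sweeps use 3-fold cross-validation at 40
epochs, which preserves the k = 3 > k = 2 ordering with large margin.
Oracle comparisons use 1000 random sequences (gapped enumeration), 100
random graphs of up to 64 nodes (graph convolution, tolerance 1e-8), and 200
random score vectors (rank-AUC).

Degenerate inputs: sequences shorter than k (or k + d − 1 for gapped
matches) produce empty graphs and are retained with a logged warning, never
silently dropped; an empty graph yields the head's constant prediction.
IUPAC ambiguity codes other than N collapse to N on input with a warning.

## Known limitations

- The interface between the graph convolutions and the 1-D convolutions is a
  deterministic lexicographic readout; other orderings (e.g. Gray-code or
  learned) are untested.
- Training is plain SGD by design; no momentum, Adam, or learning-rate
  schedules.
- No reverse-complement canonicalization: a sequence and its reverse
  complement encode to different graphs.
- k is capped at 8 (4^k node explosion); realistic use is k ≤ 4.
- Metrics assume binary labels; no multi-class support.
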