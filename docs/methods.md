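# Methods

## Model

The predictor maps an amino-acid sequence of length `L` to a solubility
score in (0, 1) and a per-residue decomposition of that score.

**Input encoding.** Sequences use the 20 standard amino acids; any other
symbol is sanitized to a single unknown token. A shared trainable
embedding matrix of shape 21 x 20 (20 residues + one PAD/unknown row)
maps tokens to 20-dimensional vectors. Batches are length-sorted and
padded at the tail; padding is excluded from every subsequent
computation (masked softmax, zeroed recurrent outputs and gradients), so
a sequence's outputs are identical whether it is scored alone or
co-batched (verified to 1e-5 in the acceptance tests).

**Two subnetworks.** Both consume the same embedded sequence and have
identical shape: a 2-layer bidirectional GRU with 20 hidden units per
direction (the second layer reads the 40-dim concatenation of both
directions of the first) followed by a per-residue affine map 40 -> 1.

- The *prediction* subnetwork P applies a LeakyReLU (negative slope
  0.01) to its per-residue scalar, giving the prediction vector `p`.
- The *attention* subnetwork A applies a sequence-wide softmax over its
  per-residue scalars (masked to real positions), giving attention
  weights `a` with `sum(a) = 1`.

**Aggregation.** The sequence score is `sigmoid(sum_i a_i * p_i)`; the
per-residue product `a_i * p_i` is the solubility profile, which sums
exactly to the logit of the score.

**Parameter count.** Each GRU direction has `3h(d + h) + 6h` parameters
(input kernel, recurrent kernel, and two bias vectors, `h = 20`,
`d = 20` for layer 1 and 40 for layer 2), each affine head has 41, and
the embedding has 420. Total: 2 subnetworks x 12,521 + 420 = **25,462**
trainable scalars, checked exactly by an acceptance test.

## Training

Binary cross-entropy on the sigmoid score, optimized with Adam
(learning rate 0.01, betas 0.9/0.999), L2 regularization 1e-6 folded
into the gradient, 50 epochs, default batch size 1001. Batches are
drawn from a fresh random permutation of the data every epoch.
Training is bit-reproducible given the model seed (initialization) and
the training seed (shuffling).

Weights are initialized with the standard recurrent-network scheme:
Glorot-uniform input kernels and affine heads, per-gate orthogonal
recurrent kernels, zero biases, embedding Uniform(-0.05, 0.05).

Because the softmax attention is positive and sums to one, the logit is
a convex combination of the per-residue predictions, and the LeakyReLU
on `p` compresses negative values by a factor of 100. Confidently
negative scores therefore require very large pre-activations and emerge
slowly; ranking (AUC) is unaffected, but the achievable cross-entropy
on separable data plateaus well above zero within the 50-epoch budget.

## Numerical choices

The network, backpropagation through time, and Adam are implemented
directly in NumPy (no deep-learning framework is required at runtime).
Gradients of every weight family are verified against central finite
differences to below 1e-7 in the test suite. Training runs in single
precision for speed; inference and all reported identities run in
double precision. Mutational scans default to single precision (about
twice as fast; their substitution deltas are differences of sigmoid
outputs read at the 1e-5 level, where single precision carries ~1e-7
noise, and a `dtype` argument restores double precision on demand). The binary cross-entropy is computed from logits via
`logaddexp` for stability, and the masked softmax subtracts the row
maximum before exponentiation.

## Synthetic data generator

Sequences are uniform random over the 20 amino acids with lengths
uniform in a range (default 50-200). The label is a Bernoulli draw with
parameter `sigmoid(steepness * (f_term - offset))`, where `f_term` is
the fraction of residues from a favorable set (default {D,E,K,R,S,T,N,Q})
within the first and last `terminal_fraction` (default 20%) of
positions. Defaults: steepness 80, offset 0.4 (the expected favorable
fraction under uniform sequences, balancing the classes), label noise 0.
At these defaults the Bayes-optimal ranking (scoring each sequence by
its own generating probability) attains AUC > 0.95, so the planted task
is learnable and the recovery benchmark is meaningful. The generator is
deliberately minimal: it makes no attempt to emulate real protein
composition, domain structure, or solubility physics — its sole purpose
is a controllable ground truth in which the signal location (termini)
is known.

## Evaluation

`compute_metrics` reports sensitivity, specificity, precision, accuracy,
balanced accuracy (mean of sensitivity and specificity), Matthews
correlation, ROC AUC, and average precision; confusion counts are
computed directly and the rank metrics come from scikit-learn. The
truncation experiments either remove `floor(0.2 * L)` residues from
each terminus or remove the central 20th-80th percentile span, then
compare the metric suite on full versus truncated sequences under the
same trained model.

Mutational scanning scores substitutions by the score change
`dS = MUT - WT`. Tandem pairs at positions `i < j` enumerate all
20 x 20 substitutions (wildtype identities included, so a full scan of
a length-L sequence covers `L*20*(L-1)*20/2` pairs, e.g. 2,101,200 at
L = 103); the epistasis term is `dE = (dS_i + dS_j) - dS_pair`. The
synergy map averages `dE` over the 400 substitution combinations per
position pair, and the separation profile averages the map per sequence
separation. Structural context uses C-beta coordinates (C-alpha for
glycine) parsed with Biopython, correlated against the synergy
separation profile with Pearson and Spearman statistics from SciPy.

## Limitations

- The model is sequence-only; no structural or evolutionary features.
- The synthetic benchmark demonstrates recovery of a planted signal,
  not real solubility prediction; no claim is made about accuracy on
  natural proteins, which would require external labelled data.
- The LeakyReLU aggregation limits confident negative predictions (see
  Training); scores for insoluble sequences cluster nearer 0.5 than 0.
- Pair scans are exhaustive and scale as `L^2 * 400` forward passes;
  full scans of long proteins are compute-bound on one CPU.
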