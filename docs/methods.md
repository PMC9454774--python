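# Methods

## Overview

The package implements a two-stage pipeline. Stage one trains a Wasserstein
GAN over fixed-length encodings of protein sequences; the critic's last
stage is a capsule network with dynamic routing. Stage two discards the
critic's final linear layer and uses its penultimate representation (the
capsule length layer) as features for a multi-label Gene Ontology
classifier, evaluated with repeated k-fold cross-validation.

## Sequence representation

Sequences are uppercased, stop characters stripped, and encoded one-hot
over a 21-symbol vocabulary: the 20 canonical amino acids in alphabetical
order plus a padding symbol at the last index. Non-canonical residue codes
(B, J, O, U, X, Z) map to padding by default; a strict mode raises instead,
naming the residue and its 1-based position. Encoding truncates at the
configured sequence length (default 160) and right-pads shorter sequences;
a separate corpus-level filter removes proteins longer than 2,000 residues
before any training. Decoding takes the argmax symbol per position (ties to
the lowest index) and drops padding symbols everywhere, so decoded strings
are always over the residue alphabet; stripping trailing padding is the
special case of this rule.

## GAN

Generator: linear map from the 128-dimensional latent vector to L×d
features, six residual blocks (conv k=5 same-padding → LeakyReLU(0.2) →
conv → LeakyReLU, additive skip scaled by 0.3), a position-wise projection
to 21 channels, and a Gumbel-softmax (τ = 1.0, no annealing, no
straight-through) producing simplex rows. Critic: initial conv, six
residual blocks, a capsule convolution, reshape into primary capsules of
dimension 8, squash, three rounds of routing-by-agreement to K output
capsules, the length layer, and a linear score head.

Losses are the Wasserstein pair: critic minimises mean(D(fake)) −
mean(D(real)) plus the two-sided gradient penalty λ·mean((‖∇_x̃D(x̃)‖₂−1)²)
at per-example uniform interpolates, λ = 10. The penalty form is the
standard one for a λ-weighted soft Lipschitz constraint; weight clipping is
available behind `lipschitz: clip` but not the default. Five critic updates
per generator update; both optimised by RMSprop (lr 1e-4, α 0.99, ε 1e-8);
an epoch is ⌊N/32⌋ full batches, drop-last. Training aborts on a non-finite
loss, naming the last good checkpoint.

Routing details: logits start at zero on every forward pass (routing is
stateless across batches); the coupling softmax is over output capsules, so
each input capsule's coefficients sum to one; the agreement update adds the
vote–output dot product after every round except the last. The squash
nonlinearity returns exactly the zero vector for zero input; an internal
ε = 1e-8 guards the norm division without appearing in the output. Capsule
vote biases are per (input, output) pair by default (`bias_mode:
per_output` ties them across inputs).

## Autodiff core

No deep-learning framework is used; `gocapgan.tensor` is a reverse-mode
autodiff over float64 NumPy arrays with a deliberately small op set
(elementwise arithmetic, exp/log/power, broadcast-aware matmul,
reshape/transpose, axis sums, gather/scatter). Every vector-Jacobian
product is built from these same ops, so gradients are themselves
differentiable — the gradient penalty's derivative with respect to critic
weights (a second-order quantity) falls out of the same machinery.
Convolution is im2col: a gather with precomputed indices, a masked
multiply for boundary positions, and a matmul. Backward closures never
reference their own output tensor (exp recomputes instead), which keeps
graphs free of reference cycles so memory is reclaimed promptly by
reference counting; the training loop additionally runs a garbage
collection per batch cycle.

## Transfer learning and classification

Features are the capsule length-layer outputs of the trained critic — the
input to the deleted final linear layer, i.e. the literal
"remove the last layer" reading; `tap: residual` instead takes the
mean-pooled residual-stack output for ablation. The classifier is a single
dense layer with sigmoid outputs trained on binary cross-entropy
(probabilities clamped to [1e-7, 1−1e-7]) with Adam (β₁ 0.9, β₂ 0.999,
ε 1e-8) for 40 epochs, mini-batches of 32. The Adam step size defaults to
0.02: 40 epochs over a desk-scale corpus of a few hundred proteins is only
a few hundred optimizer steps, and the conventional 1e-3 leaves the loss
nearly unmoved at that budget (on a linearly separable fixture it must —
and at 0.02 does — at least halve the training loss within 40 epochs).
Decision threshold 0.5 with predictions positive at probability ≥ 0.5.

Class selection keeps classes with at least 16 annotated proteins, ranks
them by descending count with lexicographic tie-break on the GO id, and
truncates to the 25 most frequent; when fewer are eligible all are returned
with a warning.

## Evaluation

Plain shuffled k-fold (k = 3) repeated 5 times with reshuffling; fold sizes
differ by at most one. Per held-out fold the four metrics are computed from
pooled (micro) confusion counts by default — precision tp/(tp+fp), recall
tp/(tp+fn), F1 their harmonic mean, Hamming loss the fraction of
protein × class slots where prediction and truth differ; macro averaging is
available by flag. Zero denominators yield 0 (never NaN) and the affected
classes are flagged in the report. Where a single "accuracy" number is
wanted it is reported as label-slot accuracy, 1 − Hamming loss. Reports
carry the per-fold table plus mean ± sd over the 15 evaluations.

## Synthetic corpus

The generator emulates the properties of a real annotated proteome that
this pipeline depends on: variable-length sequences over the 20-residue
alphabet, a long-tailed multi-label annotation table, and — crucially — a
statistically detectable sequence→function relationship, planted as one
4–8-mer motif per class inserted verbatim at a random non-overlapping
position in every annotated protein. Background residues are i.i.d.
uniform by default, so class signal cannot come from composition; a
`uniprot-like` preset with realistic residue frequencies exists. Defaults:
8 classes, 320 proteins, lengths 80–160, 1–3 labels per protein drawn with
Zipf-decaying class weights (exponent 0.7) to create frequency structure.
An exact-counts mode plants a designed number of proteins per class, used
to exercise the eligibility and top-k selection rules. Sequences too short
for their motifs are lengthened and flagged. The manifest (motifs, labels,
positions, counts) is the oracle for tests. What the corpus deliberately
lacks: domain grammar, secondary structure, homology families, and
annotation noise — so passing tests show the pipeline recovers planted
sequence signal, not that it matches published performance on UniProt.

## Problem sizes and the desk-scale regime

The shipped GAN defaults mirror the published training setup (batch 32,
sequence length 160, 12 epochs, width 64); the pipeline's desk
configuration narrows the model (width 16, capsule stage 16 output
capsules × dimension 8, J = 320 primary capsules) and trains 2 epochs on
320 proteins, about 120 critic updates — minutes on one CPU core. This
regime demonstrates the mechanics end to end but starves the critic
relative to the published setting (12 epochs × ~2,200 batches on 70,956
proteins ≈ 1.3×10⁵ critic updates): at 120 updates the critic can separate
one-hot real data from simplex generator output without developing strongly
motif-specific detectors, so the capsule-length features carry real but
modest class signal. Measured on the default design, end-to-end micro-F1
exceeds the label-permuted control by roughly 0.2 — clearly above chance,
below what longer training yields. The printed parameter counts of the
published networks (18,447,894 and 4,029,697) are not derivable from the
printed topology (widths and kernel sizes are unstated); builders report
their own analytic counts instead of asserting those numbers.

## Numerical choices

- float64 throughout; all randomness from `numpy.random.default_rng` with
  explicit seeds; training, generation, simulation and evaluation are
  bitwise reproducible given a seed.
- Gradient-penalty norm uses a 1e-24 guard inside the square root: the
  unit-norm linear-critic identity (penalty 0) and constant-critic identity
  (penalty λ) hold to 1e-9.
- Softmax subtracts the (detached) row maximum; sigmoid is computed via the
  exp of the negated absolute value; BCE clamps probabilities at 1e-7.
- Argmax ties in decoding break to the lowest vocabulary index; prediction
  threshold uses ≥.
- Fold seeds and per-stage seeds derive deterministically from the single
  run seed (multiplicative hashing mod 2³¹).

## Limitations

- The desk-scale margin over the permuted control (~0.2 micro-F1) is
  feature-limited, not classifier-limited: an independent per-class
  logistic fit on the same features reaches a similar ceiling. Longer GAN
  training is the lever, at proportional CPU cost.
- GO classes are opaque identifiers: no ontology graph, no true-path
  propagation, no protein-centric Fmax.
- Multi-label stratification is not used in the folds (plain shuffled
  k-fold), so rare classes can be absent from a fold; the zero-denominator
  convention plus per-class flags make this visible in reports.
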