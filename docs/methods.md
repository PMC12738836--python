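# Methods

This note documents the models, conventions, numerical choices and known
limitations of `plastleader`.

## Coordinates and encoding

All user-facing positions use the upstream convention: −1 is the base
immediately 5′ of the start codon, −L the far end of the window. Internally
a leader string of length L maps position −k to index L−k, so index L−1 is
always −1. One-hot channels are ordered (A, T, C, G, N) — deliberately not
alphabetical, with N reserved for unknown or padded bases. Sequences shorter
than the target length are padded on the 5′ side so the biologically
anchored 3′ end stays at a fixed array column; every interpretability
profile relies on this anchoring. Genome coordinates are 1-based inclusive
(GenBank convention). For a `+` strand CDS starting at s, the leader is
genome `[s−L, s−1]`; for a `−` strand CDS ending at e, it is the reverse
complement of `[e+1, e+L]`. Circular records wrap around the origin; on
linear records a feature with insufficient upstream sequence is skipped by
default (an N-padding mode exists, since the encoder has an N channel).
Leaders overlapping upstream genes are *not* trimmed: a fixed 300-nt window
that may include promoter elements is part of the design. IUPAC ambiguity
codes other than N are mapped to N with a warning. Deduplication removes
exact duplicates within a class, never across classes, keeping first
occurrences.

## SD scanning

The motif set is the consensus SD/SD-like list (`AGGAGG`, `GAAGGAG`,
`AAGGAG`, `AGGAG`, `AAGGA`, `AGGAAG`, `AGGA`, `GGAGG`, `GAAG`, `GGAG`,
`GAGG`, `GGA`, `AGG`), deduplicated and matched case-insensitively; N never
matches. A leader "has SD" iff at least one motif lies *fully inside* the
proximal window (default 20 nt; configurable — 30 nt is also a meaningful
choice for proximal-region accounting, and both are supported). The reported
match is the longest motif, ties broken by the 3′-most start; `has_sd` does
not depend on this tie-break.

## Synthetic benchmarks

The generator emulates the summary statistics of chloroplast leader
corpora: i.i.d. background with P(A)=P(T)=at_fraction/2 (default AT
fraction 0.70), oligo-A/oligo-T tracts of length 6–12 planted at a Poisson
rate (default 1 tract/sequence), and class-defining motifs planted uniformly
inside declared upstream windows. A class that must *lack* a motif in a
window is guaranteed clean: sequences with spurious occurrences there are
resampled (up to 100 attempts, then an error). Every planted element is
recorded in a ground-truth sidecar (id, class, motif, start, end in upstream
coordinates), which is what lets interpretability methods be scored against
known positions. Generation is byte-reproducible from the spec (including
its seed).

What the generator does **not** emulate: phylogenetic correlation between
sequences, position-specific background composition, RNA secondary
structure, and the long-tailed length variation of real 5′-UTRs. Passing
tests on these benchmarks therefore demonstrate that the pipeline recovers
*planted positional signal under realistic base composition* — not that the
model would reach the same numbers on real corpora.

## Architecture choices

Where the layer graph left open details, the package fixes them as follows:

* **Channel-wise attention** is squeeze-and-excitation: per-channel global
  average → bottleneck (reduction 16, floor of 1 unit) → sigmoid gates →
  rescaling. Gates lie in (0,1); an ablation switch forces them to 1,
  reducing the stage to plain convolution (tested).
* **Residuals**: one per convolutional stage, with 1×1 convolutions
  projecting channel counts; the second addition happens *before* pooling so
  both stages preserve length L (odd kernels, symmetric zero padding).
* **Self-attention** uses learned linear maps for Q, K and V plus an output
  projection; d_k = 2·lstm_hidden/heads (128 at the default width). V is
  required to produce an output even though only Q and K appear in the
  attention formula.
* **FC block order** is batch-norm → ReLU → dropout after each linear layer.
* **Max-pool** kernel = stride = 2; profile interpolation absorbs the length
  change.
* Softmax is evaluation-only; training consumes logits through a fused
  softmax-cross-entropy.

The network, including reverse-mode autodiff, is implemented in NumPy
(float32). The LSTM scan and scaled-dot-product attention are fused tape
nodes with hand-written backward passes; all structured operations are
gradient-checked against central finite differences (relative tolerance
2×10⁻², appropriate for float32).

## Training recipe

Adam with lr 10⁻³ and classic L2 weight decay 10⁻⁵ (decay added to the
gradient), batch 64, epoch cap 50, 80/20 stratified split, 5-fold stratified
CV. Early stopping monitors validation loss with patience 5 and restores the
best-validation weights. The LR schedule halves on a validation-loss plateau
(patience 2, floor 10⁻⁵). Gradient clipping (global norm) exists but is off
by default. Cross-validation aggregation is mean ± SD over folds, stated in
the output metadata. Divergence (non-finite loss) raises with the epoch
index. Determinism: model parameters are a pure function of the model seed,
batch order and dropout of the training seed, so a (config, data, seed)
triple reproduces histories exactly.

## Interpretability

* **CNN attention**: mean |activation| over channels of the final conv-stage
  feature maps (taken after channel attention and the residual addition,
  before pooling), linearly interpolated to L.
* **LSTM attention**: heads averaged first, then the profile value at
  position i is the average attention that position *receives* over all
  query positions, i.e. the column mean of the head-averaged matrix. (The
  row mean of a row-stochastic matrix is identically 1/L and carries no
  information; the column mean is the quantity whose class-level structure
  is interpretable.) Rows are validated to sum to 1 within 10⁻⁴.
* **Saliency** differentiates the *pre-softmax logit* of the predicted
  class: softmax probabilities saturate precisely where the model is
  confident, so their gradients vanish; logit gradients are the standard
  reading of "the model's output score". Channel-summed absolute gradients
  give one value per position.
* **Perturbation importance**: windows of size k ∈ {1, 4, 8, 12} by default
  (k = 30 is available), replacement bases i.i.d. uniform over {A,T,C,G},
  one random draw per (sequence, window) by default (`n_random` averages
  more). Coarse scan at step 3, single-position refinement where coarse
  importance exceeds 0.1, unscanned positions filled by linear interpolation
  (counted in metadata), then moving-average smoothing of width L/10 with
  shrink-to-valid edges. Note that a shrink-to-valid centred average does
  not exactly preserve a profile's mean near the edges; the smoother is
  specified by its loop-oracle definition, not by mean preservation.
* **Group profiles** are arithmetic means over class members after
  interpolation to a common length.

Heatmap/line plots orient −300 at the left and −1 at the right.

## Logos and k-mers

PFMs are tallied over a region (default −1..−30) with N excluded from
denominators and reported as a separate per-position fraction. Information
content is 2 − Shannon entropy in bits (small-sample correction off). Logos
are information-scaled by default (frequency scaling available); letter
heights are fraction × stack height. k-mer counts use overlapping windows
within the region, skip k-mers containing N, and rank by descending count
with lexicographic tie-break.

## Problem sizes used in tests and the acceptance script

The default architecture width (64 conv channels/branch, 256 LSTM units per
direction, FC 256/512) is exposed in `ModelConfig`. The test suite and
`scripts/acceptance.py` run the identical layer graph at a compact width —
16 conv channels, squeeze-excitation reduction 4, 32 LSTM units/direction,
FC 32/64 — on benchmarks of 2,000 sequences/class (length 300, AT 0.70,
discriminative motif planted in −1..−30 at probability 1) and a 1,000/class
distal control (motif at −100..−130). These sizes are the package's chosen
desk-scale study conditions: large enough that held-out accuracy, truncation
collapse to chance, and planted-window recovery by saliency/perturbation are
statistically unambiguous, small enough to run comfortably on one CPU core.
Saliency is aggregated over 400 sequences and perturbation importance over
128, where Monte-Carlo error is far below the decision margins involved.

## Known limitations

* The NumPy engine is CPU-only and single-threaded by design of its
  workloads; wall-clock cost grows quadratically in sequence length through
  the attention stage.
* Only binary classification is exercised, although `n_classes` is
  configurable.
* The SD scanner is purely positional: no position-weight-matrix scoring,
  no anti-SD duplex energetics.
* Secondary-structure features (GC content, minimum free energy) are out of
  scope.
* Multi-segment (trans-spliced) CDS features contribute only their 5′-most
  segment; pseudogene annotations are not distinguished from ordinary CDS.
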