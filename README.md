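# plastleader

Classification and interpretation of chloroplast 5′ leader sequences with a
hybrid convolutional–recurrent neural network.

## The problem

Translation initiation is a rate-limiting step for chloroplast gene
expression, and the 5′ leader — here the fixed 300-nt window immediately
upstream of a start codon, which may span the 5′-UTR and promoter elements —
carries much of the regulatory signal. Plastid translation is
prokaryote-like: many (not all) chloroplast mRNAs carry a purine-rich
Shine-Dalgarno (SD) motif such as `AGGAGG` within ~20 nt of the start codon.
Questions this package addresses for engineers of plastid expression
systems:

* Can leaders be classified by taxon of origin (plant vs. alga) or by SD
  status, and which sequence positions drive the classification?
* Does the proximal −1..−30 window carry the class signal, so that hybrid
  leaders (distal part from one source, proximal −1..−30 from another) are a
  rational design strategy?

`plastleader` provides the full pipeline at desk scale: leader extraction
from annotated genomes, SD partitioning, a CNN-LSTM-attention-residual
classifier, training/cross-validation/metrics, and three interpretability
methods — all testable on synthetic benchmarks with planted, position-known
motifs, so no genome download is required.

## The model

Input is one-hot encoded over channels (A, T, C, G, N), shape `(n, 300, 5)`,
with short sequences 5′-padded by N so array column L−1 is always position −1.
The network is

1. conv(k=3) → batch-norm → ReLU, plus a 1×1-projected residual;
2. parallel convs (k=3,5,7, same-length) → concat → channel-wise
   (squeeze-and-excitation) attention → batch-norm → residual → max-pool(2)
   → dropout 0.5;
3. bidirectional LSTM (256 hidden/direction by default);
4. 4-head scaled-dot-product self-attention,
   αᵢⱼ = softmax(QKᵀ/√d_k), mean-pooled into a context vector;
5. FC 256 → FC 512 (batch-norm, ReLU, dropout 0.3 each) → linear head →
   softmax.

Training: cross-entropy, Adam (lr 10⁻³, weight decay 10⁻⁵), batch 64, up to
50 epochs, 80/20 stratified split, 5-fold stratified CV, plateau-halving LR
schedule and early stopping on validation loss.

Interpretability, with every profile on the −1..−300 coordinate system:

* **CNN attention** `A_i = (1/C) Σ_c |F_ic|` — mean absolute activation of
  the final conv feature maps;
* **LSTM attention** — the self-attention each position receives, averaged
  over heads and query positions;
* **saliency** `S_i = |∂f(x)/∂x_i|` of the predicted-class logit, summed
  over nucleotide channels;
* **perturbation importance** `I_i` — the accuracy drop after replacing a
  k-nt window at position i with uniform random bases (coarse scan step 3,
  single-nt refinement where `I > 0.1`, moving-average smoothing L/10).

The neural-network core (reverse-mode autodiff, conv/LSTM/attention layers,
Adam) is implemented in NumPy inside `plastleader.nn` and is
gradient-checked against finite differences in the test suite.

## Worked example

```python
import numpy as np
from plastleader import motif_benchmark_spec, generate_dataset, encode
from plastleader.model import ModelConfig
from plastleader.training import TrainConfig, truncation_experiment

# 2,000 leaders/class, 70% AT; the only class signal is AGGAGG in -1..-30
data = generate_dataset(motif_benchmark_spec(n_per_class=2000, seed=101))
config = ModelConfig(conv_channels=16, channel_attention_reduction=4,
                     lstm_hidden=32, attention_heads=4, fc_sizes=(32, 64), seed=5)
result = truncation_experiment(data.leaders, config,
                               TrainConfig(epochs=10, seed=5), remove=30)
print(f"full-length accuracy  {result.full_report.accuracy:.3f}")
print(f"truncated accuracy    {result.truncated_report.accuracy:.3f}")
```

prints

```
full-length accuracy  0.999
truncated accuracy    0.519
```

full-length leaders are classified almost perfectly, while removing the
proximal 30 nt (the planted window) collapses the classifier to chance —
the desk-scale analogue of the finding that the −1..−30 region carries the
taxon signal. Group saliency and perturbation importance on the trained
model peak inside the planted window (see `plastleader.interpret`).

A CLI mirrors the library: `plastleader simulate | extract | partition |
truncate | hybridize | train | evaluate | cv | truncation-experiment |
interpret | perturb | logo | kmers` (see `plastleader --help`).

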