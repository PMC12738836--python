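"""Model explanation: attention profiles, gradient saliency, perturbation importance.

Three complementary views of what the classifier uses:

* **Convolutional attention** — mean absolute activation across channels of
  the final convolutional feature maps, a spatial footprint of detected
  local patterns.
* **Recurrent attention** — the self-attention each position *receives*,
  averaged over heads and query positions.
* **Gradient saliency** — |d logit(predicted class) / d input|, summed over
  the five nucleotide channels.
* **Perturbation importance** — the drop in classification accuracy when a
  k-nt window at a position is replaced by uniformly random bases
  (in-silico mutagenesis), scanned coarsely and refined where informative.

All profiles are reported on the input coordinate system: a profile of
length L with index j <-> upstream position -(L - j) (index L-1 is -1, the
base next to the start codon). Shorter internal tracks (after pooling) are
rescaled to L by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import EncodedBatch
from .model import ForwardTrace, LeaderNet, forward_trace
from .nn import autograd as ag


@dataclass
class PositionProfile:
    """A per-position score track of length L (index j <-> position -(L-j))."""

    values: np.ndarray
    kind: str  # cnn_attention | lstm_attention | saliency | importance
    class_label: str | None = None
    n_aggregated: int = 1
    window_size: int | None = None  # importance profiles only
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def positions(self) -> np.ndarray:
        """Upstream positions -L..-1 aligned with ``values``."""
        L = len(self.values)
        return np.arange(-L, 0)

    def argmax_position(self) -> int:
        """Upstream position of the profile's maximum."""
        return int(self.positions[int(self.values.argmax())])


def interpolate_to_length(values: np.ndarray, length: int) -> np.ndarray:
    """Linearly rescale a track to ``length`` samples (endpoints pinned)."""
    values = np.asarray(values, dtype=np.float64)
    if len(values) == length:
        return values.copy()
    src = np.linspace(0.0, 1.0, num=len(values))
    dst = np.linspace(0.0, 1.0, num=length)
    return np.interp(dst, src, values)


def cnn_attention(trace: ForwardTrace, length: int | None = None) -> list[PositionProfile]:
    """Spatial attention from the final conv stage: mean |activation| over
    channels, interpolated to the input length."""
    F = trace.conv_features  # (n, L_f, C)
    if F is None or F.size == 0:
        raise ValueError("trace carries no convolutional features")
    length = length or F.shape[1]
    scores = np.abs(F).mean(axis=2)  # (n, L_f)
    return [PositionProfile(interpolate_to_length(s, length), kind="cnn_attention")
            for s in scores]


def lstm_attention(trace: ForwardTrace, length: int | None = None,
                   row_tolerance: float = 1e-4) -> list[PositionProfile]:
    """Positional importance from self-attention: heads are averaged first,
    then the attention each position receives is averaged over all query
    positions; interpolated to the input length."""
    alpha = trace.attention  # (n, heads, T, T)
    if alpha is None:
        raise ValueError("trace carries no attention matrices")
    row_sums = alpha.sum(axis=-1)
    if np.abs(row_sums - 1.0).max() > row_tolerance:
        raise ValueError("attention rows are not normalised")
    mean_heads = alpha.mean(axis=1)          # (n, T, T)
    received = mean_heads.mean(axis=1)       # (n, T): column mean over queries
    length = length or received.shape[1]
    return [PositionProfile(interpolate_to_length(r, length), kind="lstm_attention")
            for r in received]


def group_profile(profiles: list[PositionProfile], labels: list[str],
                  length: int | None = None) -> dict[str, PositionProfile]:
    """Per-class arithmetic mean of (interpolated) per-sample profiles."""
    if len(profiles) != len(labels):
        raise ValueError("profiles and labels must be aligned")
    kinds = {p.kind for p in profiles}
    if len(kinds) != 1:
        raise ValueError(f"cannot aggregate mixed profile kinds {kinds}")
    kind = kinds.pop()
    length = length or max(len(p) for p in profiles)
    out: dict[str, PositionProfile] = {}
    for label in sorted(set(labels)):
        members = [interpolate_to_length(p.values, length)
                   for p, l in zip(profiles, labels) if l == label]
        out[label] = PositionProfile(np.mean(members, axis=0), kind=kind,
                                     class_label=label, n_aggregated=len(members))
    return out


def saliency(model: LeaderNet, batch: EncodedBatch | np.ndarray) -> list[PositionProfile]:
    """|gradient| of the predicted-class logit w.r.t. the input, summed over
    the five nucleotide channels.

    The pre-softmax logit is differentiated (softmax probabilities saturate
    and their gradients vanish exactly where the model is most confident).
    """
    data = batch.data if isinstance(batch, EncodedBatch) else np.asarray(batch)
    was_training = model.training
    model.eval()
    try:
        x = ag.Tensor(data, requires_grad=True)
        logits = model(x)
        pred = logits.data.argmax(axis=1)
        picked = logits[np.arange(len(pred)), pred]
        ag.tsum(picked).backward()
    finally:
        model.train(was_training)
    grads = np.abs(x.grad).sum(axis=2)  # (n, L)
    return [PositionProfile(g, kind="saliency") for g in grads]


def group_saliency(per_sample: list[PositionProfile],
                   labels: list[str]) -> dict[str, PositionProfile]:
    """Class-mean saliency (channel summation already done per sample)."""
    return group_profile(per_sample, labels)


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrink-to-valid edges."""
    values = np.asarray(values, dtype=np.float64)
    if window <= 1:
        return values.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = len(values)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def perturbation_importance(model: LeaderNet, batch: EncodedBatch,
                            window_sizes: tuple[int, ...] = (1, 4, 8, 12),
                            coarse_step: int = 3, refine_threshold: float = 0.1,
                            smooth_window: int | None = None, n_random: int = 1,
                            seed: int = 0,
                            batch_size: int = 256) -> dict[int, PositionProfile]:
    """In-silico mutagenesis importance, one profile per mutation window size.

    For a window of size k starting at index i, the k positions are replaced
    in every sequence by i.i.d. uniform draws over {A, T, C, G}; the
    importance I_i is the drop in accuracy (fraction correct before minus
    after). A coarse scan (step ``coarse_step``) is refined at single-position
    resolution wherever coarse importance exceeds ``refine_threshold``;
    unscanned positions are filled by linear interpolation (flagged in
    metadata) and the profile is smoothed by a moving average of width L/10
    with shrink-to-valid edges.
    """
    if len(batch) == 0:
        raise ValueError("empty dataset")
    data, labels = batch.data, batch.labels
    n, L, _ = data.shape
    if max(window_sizes) > L:
        raise ValueError("mutation window exceeds sequence length")
    smooth_window = smooth_window or max(L // 10, 1)
    rng = np.random.default_rng(seed)
    base_correct = float((model.predict(data, batch_size) == labels).mean())

    def importance_at(i: int, k: int) -> float:
        drops = []
        for _ in range(max(n_random, 1)):
            mutated = data.copy()
            draws = rng.integers(0, 4, size=(n, k))  # channels A,T,C,G
            mutated[:, i:i + k, :] = 0.0
            rows = np.repeat(np.arange(n), k)
            cols = np.tile(np.arange(i, i + k), n)
            mutated[rows, cols, draws.ravel()] = 1.0
            mut_correct = float((model.predict(mutated, batch_size) == labels).mean())
            drops.append(base_correct - mut_correct)
        return float(np.mean(drops))

    out: dict[int, PositionProfile] = {}
    for k in window_sizes:
        starts = np.arange(0, L - k + 1, coarse_step)
        scanned = {int(i): importance_at(int(i), k) for i in starts}
        # refine around informative coarse hits
        hot = [i for i, v in scanned.items() if v > refine_threshold]
        for i in hot:
            for j in range(max(i - coarse_step + 1, 0),
                           min(i + coarse_step, L - k + 1)):
                if j not in scanned:
                    scanned[j] = importance_at(j, k)
        xs = np.array(sorted(scanned))
        ys = np.array([scanned[i] for i in xs])
        full = np.interp(np.arange(L), xs, ys)
        smoothed = moving_average(full, smooth_window)
        scanned_mask = np.zeros(L, dtype=bool)
        scanned_mask[xs] = True
        out[k] = PositionProfile(
            smoothed, kind="importance", window_size=k,
            n_aggregated=n,
            metadata={"scanned_mask": scanned_mask, "raw": full,
                      "base_accuracy": base_correct,
                      "interpolated_positions": int((~scanned_mask).sum())},
        )
    return out


def export_profile_tsv(profile: PositionProfile, path) -> None:
    """Write (position, value) rows, -1 first (adjacent to the start codon)."""
    import pandas as pd

    pd.DataFrame({
        "position": profile.positions[::-1],
        "value": profile.values[::-1],
    }).to_csv(path, sep="\t", index=False)


def plot_profiles(profiles: dict[str, PositionProfile], path, title: str = "") -> None:
    """Line plot of group profiles, -300 at the left and -1 at the right."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    for name, p in profiles.items():
        ax.plot(p.positions, p.values, label=str(name))
    ax.set_xlabel("position relative to start codon (bp)")
    ax.set_ylabel(profiles[next(iter(profiles))].kind.replace("_", " "))
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
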