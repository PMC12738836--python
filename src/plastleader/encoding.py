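"""One-hot encoding of leader sequences.

Channel order is (A, T, C, G, N) — note: not alphabetical. Sequences shorter
than the target length are left-padded (5' side) with N so that array column
``L - 1`` always holds the biologically anchored position -1; array index j
corresponds to upstream position -(L - j). Every interpretability profile in
the package relies on this anchoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import LeaderSequence

CHANNELS = "ATCGN"
_CHANNEL_INDEX = {b: i for i, b in enumerate(CHANNELS)}


@dataclass
class EncodedBatch:
    """Rank-3 one-hot array (n, L, 5) with aligned ids and integer labels."""

    data: np.ndarray
    ids: list[str]
    labels: np.ndarray
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3 or self.data.shape[2] != len(CHANNELS):
            raise ValueError(f"expected (n, L, 5) data, got {self.data.shape}")
        if not (len(self.ids) == self.data.shape[0] == len(self.labels)):
            raise ValueError("ids, labels and data are not aligned")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def seq_length(self) -> int:
        return self.data.shape[1]

    def subset(self, indices) -> "EncodedBatch":
        indices = np.asarray(indices, dtype=np.intp)
        return EncodedBatch(self.data[indices], [self.ids[int(i)] for i in indices],
                            self.labels[indices], self.label_names)


def save_batch(batch: EncodedBatch, path) -> None:
    """Compressed array dump of an encoded batch, for caching."""
    np.savez_compressed(path, data=batch.data, ids=np.array(batch.ids),
                        labels=batch.labels,
                        label_names=np.array(batch.label_names))


def load_batch(path) -> EncodedBatch:
    with np.load(path, allow_pickle=False) as f:
        return EncodedBatch(f["data"], [str(i) for i in f["ids"]], f["labels"],
                            [str(n) for n in f["label_names"]])


def encode(sequences: list[LeaderSequence], target_length: int | None = None,
           label_names: list[str] | None = None) -> EncodedBatch:
    """One-hot encode leaders, 5'-padding short ones with N to ``target_length``.

    Labels are mapped to indices by sorted order of the distinct labels unless
    an explicit ``label_names`` order is given. Over-length sequences are
    rejected rather than trimmed.
    """
    if target_length is None:
        target_length = max(len(s) for s in sequences)
    if label_names is None:
        label_names = sorted({s.label for s in sequences})
    label_index = {name: i for i, name in enumerate(label_names)}
    data = np.zeros((len(sequences), target_length, len(CHANNELS)), dtype=np.float32)
    labels = np.empty(len(sequences), dtype=np.int64)
    ids = []
    for n, leader in enumerate(sequences):
        seq = leader.sequence
        if len(seq) > target_length:
            raise ValueError(
                f"sequence {leader.id!r} ({len(seq)} nt) exceeds target length {target_length}"
            )
        pad = target_length - len(seq)
        data[n, :pad, _CHANNEL_INDEX["N"]] = 1.0
        for j, base in enumerate(seq):
            try:
                data[n, pad + j, _CHANNEL_INDEX[base]] = 1.0
            except KeyError:
                raise ValueError(f"illegal character {base!r} in {leader.id!r}") from None
        ids.append(leader.id)
        labels[n] = label_index[leader.label]
    return EncodedBatch(data, ids, labels, list(label_names))


def decode(batch: EncodedBatch | np.ndarray, strip_padding: bool = True) -> list[str]:
    """Invert :func:`encode`; validates that every row is exactly one-hot."""
    data = batch.data if isinstance(batch, EncodedBatch) else np.asarray(batch)
    if not np.all(np.isin(data, (0.0, 1.0))) or not np.all(data.sum(axis=2) == 1.0):
        raise ValueError("batch rows are not one-hot")
    idx = data.argmax(axis=2)
    out = []
    for row in idx:
        seq = "".join(CHANNELS[i] for i in row)
        if strip_padding and set(seq) != {"N"}:
            seq = seq.lstrip("N")  # remove 5' padding; an all-N row is kept as-is
        out.append(seq)
    return out
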