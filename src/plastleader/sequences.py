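"""Leader-sequence container and FASTA/TSV interchange.

A *leader* is the fixed-length window immediately 5' of a start codon
(default 300 nt). Positions are reported in the upstream convention:
-1 is the base adjacent to the start codon, -L the 5'-most base of the
window. For a string ``s`` of length L, position -k is ``s[L - k]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")


@dataclass
class LeaderSequence:
    """One upstream leader with its class label and provenance."""

    id: str
    sequence: str
    label: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(f"leader {self.id!r} contains illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        """Base at upstream position ``-k`` (pass k as a negative integer)."""
        if not -len(self.sequence) <= position <= -1:
            raise IndexError(f"position {position} outside -1..-{len(self.sequence)}")
        return self.sequence[len(self.sequence) + position]


def position_to_index(position: int, length: int) -> int:
    """Map upstream position -k to the 0-based string/array index."""
    if not -length <= position <= -1:
        raise IndexError(f"position {position} outside -1..-{length}")
    return length + position


def index_to_position(index: int, length: int) -> int:
    """Map a 0-based string/array index to its upstream position -k."""
    if not 0 <= index < length:
        raise IndexError(f"index {index} outside 0..{length - 1}")
    return index - length


def write_leaders_fasta(leaders: Iterable[LeaderSequence], path: str | Path) -> None:
    """Write leaders as FASTA; the header carries ``id label=<label>``."""
    records = [
        SeqRecord(Seq(ld.sequence), id=ld.id, description=f"label={ld.label}")
        for ld in leaders
    ]
    SeqIO.write(records, str(path), "fasta")


def write_label_table(leaders: Iterable[LeaderSequence], path: str | Path) -> None:
    rows = [{"id": ld.id, "label": ld.label, "length": len(ld)} for ld in leaders]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_leaders_fasta(path: str | Path, labels: str | Path | dict | None = None,
                       default_label: str = "unlabelled") -> list[LeaderSequence]:
    """Read leaders from FASTA, taking labels from the header ``label=`` tag,
    an id->label mapping, or a TSV label table with columns (id, label)."""
    if isinstance(labels, (str, Path)):
        table = pd.read_csv(labels, sep="\t")
        labels = dict(zip(table["id"].astype(str), table["label"].astype(str)))
    leaders = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = None
        for token in rec.description.split():
            if token.startswith("label="):
                label = token[len("label="):]
        if labels is not None:
            label = labels.get(rec.id, label)
        leaders.append(LeaderSequence(id=rec.id, sequence=str(rec.seq),
                                      label=label or default_label))
    return leaders
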