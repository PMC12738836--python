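"""Shine-Dalgarno motif scanning, dataset partitioning and leader surgery.

Plastid translation is prokaryote-like: many (not all) chloroplast mRNAs
carry a purine-rich SD or SD-like element within ~20 nt of the start codon.
The scanner here asks a purely positional question: does any motif of a
consensus set occur *fully inside* the proximal window (-1..-window)?

The module also builds the derived datasets used downstream: balanced
two-class subsets, 3'-truncated leaders (the proximal ``remove`` nt deleted)
and proximal/distal hybrid leaders.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .sequences import LeaderSequence

#: Consensus SD and SD-like motifs (duplicates removed, order preserved).
CANONICAL_SD_MOTIFS: tuple[str, ...] = (
    "AGGAGG", "GAAGGAG", "AAGGAG", "AGGAG", "AAGGA", "AGGAAG", "AGGA",
    "GGAGG", "GAAG", "GGAG", "GAGG", "GGA", "AGG",
)


@dataclass(frozen=True)
class MotifSet:
    """Ordered, deduplicated, uppercase motif collection."""

    motifs: tuple[str, ...] = CANONICAL_SD_MOTIFS

    def __post_init__(self):
        seen: dict[str, None] = {}
        for m in self.motifs:
            m = m.upper()
            if not m or set(m) - set("ACGT"):
                raise ValueError(f"motif {m!r} is not a non-empty ACGT string")
            seen.setdefault(m, None)
        object.__setattr__(self, "motifs", tuple(seen))

    def __iter__(self):
        return iter(self.motifs)


@dataclass(frozen=True)
class SDAnnotation:
    """Result of scanning one leader's proximal window."""

    has_sd: bool
    matched_motif: str = ""
    match_start: int | None = None  # upstream position of the motif's 5' end
    window: int = 20


def scan_sd(leader: LeaderSequence | str, motifs: MotifSet | None = None,
            window: int = 20) -> SDAnnotation:
    """Scan the last ``window`` nt for any motif occurring fully inside it.

    ``has_sd`` is True iff at least one motif is contained in the window.
    For reporting, the longest matching motif is chosen, ties broken by the
    3'-most start (closest to the start codon); ``match_start`` is the
    upstream position of its 5'-most base. N never matches.
    """
    seq = leader.sequence if isinstance(leader, LeaderSequence) else leader.upper()
    if window > len(seq):
        raise ValueError(f"window {window} exceeds leader length {len(seq)}")
    motifs = motifs or MotifSet()
    tail = seq[len(seq) - window:]
    best: tuple[int, int, str] | None = None  # (len, start-in-tail, motif)
    for motif in motifs:
        start = tail.rfind(motif)
        if start < 0:
            continue
        key = (len(motif), start, motif)
        if best is None or key > best:
            best = key
    if best is None:
        return SDAnnotation(has_sd=False, window=window)
    mlen, start, motif = best
    return SDAnnotation(has_sd=True, matched_motif=motif,
                        match_start=start - window, window=window)


def annotate_sd(leaders: list[LeaderSequence], motifs: MotifSet | None = None,
                window: int = 20) -> pd.DataFrame:
    """Tabulate scan_sd over a dataset (columns: id, has_sd, motif, start)."""
    rows = []
    for ld in leaders:
        ann = scan_sd(ld, motifs, window)
        rows.append({"id": ld.id, "has_sd": ann.has_sd, "motif": ann.matched_motif,
                     "start": ann.match_start})
    return pd.DataFrame(rows, columns=["id", "has_sd", "motif", "start"])


def partition_by_sd(leaders: list[LeaderSequence], motifs: MotifSet | None = None,
                    window: int = 20) -> tuple[list[LeaderSequence], list[LeaderSequence]]:
    """Disjoint, exhaustive split into (with-SD, without-SD) by :func:`scan_sd`."""
    with_sd, without_sd = [], []
    for ld in leaders:
        (with_sd if scan_sd(ld, motifs, window).has_sd else without_sd).append(ld)
    return with_sd, without_sd


def balance_classes(a: list[LeaderSequence], b: list[LeaderSequence],
                    n_per_class: int, seed: int,
                    labels: tuple[str, str] | None = None) -> list[LeaderSequence]:
    """Sample ``n_per_class`` members uniformly without replacement from each side.

    The result interleaves nothing: it is the two shuffled samples
    concatenated, deterministic under ``seed``. If ``labels`` is given the
    sampled leaders are relabelled accordingly.
    """
    if n_per_class > min(len(a), len(b)):
        raise ValueError(
            f"n_per_class={n_per_class} exceeds the smaller class ({min(len(a), len(b))})"
        )
    rng = np.random.default_rng(seed)
    out: list[LeaderSequence] = []
    for group, label in zip((a, b), labels or (None, None)):
        idx = rng.permutation(len(group))[:n_per_class]
        for i in idx:
            ld = group[int(i)]
            out.append(dc_replace(ld, label=label) if label is not None else ld)
    return out


def truncate_leader(leader: LeaderSequence, remove: int = 30) -> LeaderSequence:
    """Delete the ``remove`` 3'-most bases (positions -1..-remove)."""
    if remove < 0 or remove >= len(leader):
        raise ValueError(f"remove={remove} must lie in [0, leader length)")
    if remove == 0:
        return leader
    return dc_replace(
        leader,
        sequence=leader.sequence[:len(leader) - remove],
        provenance={**leader.provenance, "truncated_by": remove},
    )


def make_hybrid(proximal_donor: LeaderSequence, distal_donor: LeaderSequence,
                junction: int = 30) -> LeaderSequence:
    """Fuse the distal part of one leader with the proximal part of another.

    The output takes positions -L..-(junction+1) from ``distal_donor`` and
    positions -junction..-1 from ``proximal_donor``; total length preserved.
    """
    if len(proximal_donor) != len(distal_donor):
        raise ValueError("hybrid donors must have the same length")
    L = len(proximal_donor)
    if not 0 <= junction <= L:
        raise ValueError(f"junction={junction} must lie in [0, {L}]")
    seq = distal_donor.sequence[:L - junction] + proximal_donor.sequence[L - junction:]
    return LeaderSequence(
        id=f"hybrid:{distal_donor.id}|{proximal_donor.id}",
        sequence=seq,
        label=f"hybrid_{junction}",
        provenance={"proximal_donor": proximal_donor.id,
                    "distal_donor": distal_donor.id, "junction": junction},
    )


def harvest_misclassified(predictions, true_labels, leaders: list[LeaderSequence],
                          motifs: MotifSet | None = None,
                          window: int = 20) -> dict[tuple, pd.DataFrame]:
    """Collect, per ordered (true, predicted) class pair, the misclassified
    leaders with their SD annotation — the with/without-SD breakdown of a
    model's errors.
    """
    predictions = list(predictions)
    true_labels = list(true_labels)
    if not len(predictions) == len(true_labels) == len(leaders):
        raise ValueError("predictions, labels and leaders must be aligned")
    out: dict[tuple, list[dict]] = {}
    classes = sorted(set(true_labels) | set(predictions))
    for t in classes:
        for p in classes:
            if t != p:
                out[(t, p)] = []
    for pred, true, ld in zip(predictions, true_labels, leaders):
        if pred == true:
            continue
        ann = scan_sd(ld, motifs, window)
        out[(true, pred)].append({"id": ld.id, "true": true, "predicted": pred,
                                  "has_sd": ann.has_sd, "motif": ann.matched_motif,
                                  "start": ann.match_start})
    cols = ["id", "true", "predicted", "has_sd", "motif", "start"]
    return {k: pd.DataFrame(v, columns=cols) for k, v in out.items()}
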