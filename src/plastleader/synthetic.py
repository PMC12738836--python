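"""Synthetic leader-sequence benchmarks with planted, position-controlled motifs.

The generator emulates the summary statistics of chloroplast leader corpora:
~70% AT content, oligo-A/oligo-T tracts (length >= 6), and optional
Shine-Dalgarno-like motifs confined to the proximal window. Class signal is
injected by planting class-specific motifs inside declared upstream windows,
and every planted element is recorded in a ground-truth sidecar so that
interpretability methods can be scored against known positions.

Background model: i.i.d. per-position draws with P(A)=P(T)=at_fraction/2 and
P(C)=P(G)=(1-at_fraction)/2. Oligo tracts and motifs are planted on top of
the background. A sequence of a class that forbids a motif in some window is
resampled (up to 100 attempts) if the motif occurs there spuriously, keeping
class labels exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import LeaderSequence, position_to_index, write_leaders_fasta

BASES = np.array(list("ATCG"))


@dataclass(frozen=True)
class MotifPlan:
    """A motif to plant: window bounds are inclusive upstream positions."""

    motif: str
    window: tuple[int, int]
    probability: float = 1.0


@dataclass
class SyntheticSpec:
    """Full description of a synthetic dataset; generation is a pure function of it."""

    n_per_class: int
    length: int = 300
    at_fraction: float = 0.70
    class_motifs: dict[str, list[MotifPlan]] = field(default_factory=dict)
    forbidden_motifs: dict[str, list[tuple[str, tuple[int, int]]]] = field(default_factory=dict)
    sd_planting_rate: float = 0.0
    sd_motif: str = "AGGAGG"
    sd_window: tuple[int, int] = (-20, -1)
    oligo_tract_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ValueError("at_fraction must lie in [0, 1]")
        if not 0.0 <= self.sd_planting_rate <= 1.0:
            raise ValueError("sd_planting_rate must lie in [0, 1]")
        for label, plans in self.class_motifs.items():
            for plan in plans:
                if not 0.0 <= plan.probability <= 1.0:
                    raise ValueError(f"planting probability of {plan.motif!r} outside [0, 1]")
                _legal_starts(plan.motif, plan.window, self.length)  # validates

    @property
    def labels(self) -> list[str]:
        labels = sorted(set(self.class_motifs) | set(self.forbidden_motifs))
        return labels or ["class0"]

    def to_json(self) -> str:
        d = asdict(self)
        d["class_motifs"] = {
            k: [asdict(p) for p in v] for k, v in self.class_motifs.items()
        }
        return json.dumps(d, indent=2)


@dataclass
class SyntheticDataset:
    leaders: list[LeaderSequence]
    truth: pd.DataFrame  # columns: id, label, kind, motif, start, end
    spec: SyntheticSpec

    def write(self, outdir: str | Path, stem: str = "synthetic") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_leaders_fasta(self.leaders, outdir / f"{stem}.fa")
        self.truth.to_csv(outdir / f"{stem}.truth.tsv", sep="\t", index=False)
        (outdir / f"{stem}.spec.json").write_text(self.spec.to_json())


def _legal_starts(motif: str, window: tuple[int, int], length: int) -> range:
    """0-based string start indices at which ``motif`` fits fully inside ``window``."""
    lo, hi = min(window), max(window)
    if lo < -length or hi > -1:
        raise ValueError(f"window {window} outside -1..-{length}")
    lo_idx = position_to_index(lo, length)
    hi_idx = position_to_index(hi, length)
    if hi_idx - lo_idx + 1 < len(motif):
        raise ValueError(f"window {window} too small for motif {motif!r}")
    return range(lo_idx, hi_idx - len(motif) + 2)


def plant_motif(sequence: str, motif: str, window: tuple[int, int],
                seed: int | np.random.Generator = 0) -> tuple[str, int]:
    """Overwrite a uniformly chosen legal placement of ``window`` with ``motif``.

    Returns the new sequence and the chosen 0-based start index. An empty
    motif leaves the sequence unchanged (start index -1).
    """
    if not motif:
        return sequence, -1
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = _legal_starts(motif, window, len(sequence))
    start = int(rng.integers(starts.start, starts.stop))
    return sequence[:start] + motif + sequence[start + len(motif):], start


def _occurs_in_window(sequence: str, motif: str, window: tuple[int, int]) -> bool:
    lo, hi = min(window), max(window)
    L = len(sequence)
    lo_idx = position_to_index(lo, L)
    hi_idx = position_to_index(hi, L)
    return motif in sequence[lo_idx:hi_idx + 1]


def _truth_positions(start_idx: int, motif_len: int, length: int) -> tuple[int, int]:
    """Upstream (5'-most, 3'-most) positions of a planted element."""
    return start_idx - length, start_idx + motif_len - 1 - length


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw the dataset described by ``spec``; byte-identical under the same seed."""
    rng = np.random.default_rng(spec.seed)
    probs = np.array([spec.at_fraction / 2, spec.at_fraction / 2,
                      (1 - spec.at_fraction) / 2, (1 - spec.at_fraction) / 2])
    leaders: list[LeaderSequence] = []
    truth_rows: list[dict] = []
    for label in spec.labels:
        plans = list(spec.class_motifs.get(label, []))
        if spec.sd_planting_rate > 0:
            plans.append(MotifPlan(spec.sd_motif, spec.sd_window, spec.sd_planting_rate))
        forbidden = spec.forbidden_motifs.get(label, [])
        for i in range(spec.n_per_class):
            seq_id = f"{label}_{i:05d}"
            for attempt in range(100):
                seq, rows = _draw_one(rng, spec, probs, plans, seq_id, label)
                if not any(_occurs_in_window(seq, m, w) for m, w in forbidden):
                    break
            else:
                raise RuntimeError(
                    f"could not draw a sequence for class {label!r} avoiding "
                    f"forbidden motifs after 100 attempts"
                )
            leaders.append(LeaderSequence(id=seq_id, sequence=seq, label=label,
                                          provenance={"synthetic": True}))
            truth_rows.extend(rows)
    truth = pd.DataFrame(truth_rows,
                         columns=["id", "label", "kind", "motif", "start", "end"])
    return SyntheticDataset(leaders=leaders, truth=truth, spec=spec)


def _draw_one(rng: np.random.Generator, spec: SyntheticSpec, probs: np.ndarray,
              plans: list[MotifPlan], seq_id: str, label: str):
    L = spec.length
    arr = rng.choice(BASES, size=L, p=probs)
    rows: list[dict] = []
    # oligo-A / oligo-T tracts (length >= 6)
    for _ in range(rng.poisson(spec.oligo_tract_rate)):
        tract_len = int(rng.integers(6, 13))
        base = "A" if rng.random() < 0.5 else "T"
        start = int(rng.integers(0, L - tract_len + 1))
        arr[start:start + tract_len] = base
        s5, s3 = _truth_positions(start, tract_len, L)
        rows.append({"id": seq_id, "label": label, "kind": "tract",
                     "motif": base * tract_len, "start": s5, "end": s3})
    seq = "".join(arr)
    # planted motifs (planted last so they are verbatim); non-overlapping
    occupied: list[tuple[int, int]] = []
    for plan in plans:
        if rng.random() >= plan.probability:
            continue
        for _ in range(100):
            candidate, start = plant_motif(seq, plan.motif, plan.window, rng)
            span = (start, start + len(plan.motif))
            if all(span[1] <= a or span[0] >= b for a, b in occupied):
                seq = candidate
                occupied.append(span)
                break
        else:
            raise RuntimeError(f"could not place motif {plan.motif!r} without overlap")
        s5, s3 = _truth_positions(start, len(plan.motif), L)
        rows.append({"id": seq_id, "label": label, "kind": "motif",
                     "motif": plan.motif, "start": s5, "end": s3})
    return seq, rows


def motif_benchmark_spec(n_per_class: int, motif: str = "AGGAGG",
                         window: tuple[int, int] = (-30, -1), length: int = 300,
                         at_fraction: float = 0.70, oligo_tract_rate: float = 1.0,
                         seed: int = 0) -> SyntheticSpec:
    """Two-class benchmark whose only class signal is ``motif`` inside ``window``.

    Class ``motif`` carries the motif (planting probability 1); class
    ``background`` is guaranteed free of it inside the window, so outside the
    window both classes share identical statistics.
    """
    return SyntheticSpec(
        n_per_class=n_per_class, length=length, at_fraction=at_fraction,
        class_motifs={"motif": [MotifPlan(motif, window, 1.0)], "background": []},
        forbidden_motifs={"background": [(motif, window)]},
        oligo_tract_rate=oligo_tract_rate, seed=seed,
    )
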