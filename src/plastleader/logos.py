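"""Position-frequency matrices, sequence logos and k-mer abundance.

Regions use the upstream convention: ``(-30, -1)`` is the 30 nt adjacent to
the start codon, i.e. the last 30 characters of a leader. N bases are
excluded from frequency denominators and from k-mer windows and tracked as
a separate per-position fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import LeaderSequence, position_to_index

PFM_BASES = "ACGT"


@dataclass
class PositionFrequencyMatrix:
    """Per-position base statistics over a fixed upstream region.

    ``frequencies`` rows are positions (5'->3' within the region), columns
    A, C, G, T; ``information`` is the Shannon information content in bits
    (2 - entropy), zero where no non-N base was seen.
    """

    region: tuple[int, int]            # (most 5', most 3') upstream positions
    counts: pd.DataFrame               # integer tallies, incl. an 'N' column
    frequencies: pd.DataFrame          # A,C,G,T fractions (N excluded)
    n_fraction: np.ndarray             # per-position fraction of N
    information: np.ndarray            # bits in [0, 2]
    n_sequences: int

    @property
    def positions(self) -> np.ndarray:
        lo, hi = min(self.region), max(self.region)
        return np.arange(lo, hi + 1)

    def to_tsv(self, path: str | Path) -> None:
        df = self.frequencies.copy()
        df.insert(0, "position", self.positions)
        df["information"] = self.information
        df["n_fraction"] = self.n_fraction
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PositionFrequencyMatrix":
        df = pd.read_csv(path, sep="\t")
        region = (int(df["position"].iloc[0]), int(df["position"].iloc[-1]))
        freqs = df[list(PFM_BASES)].reset_index(drop=True)
        return cls(region=region, counts=pd.DataFrame(),
                   frequencies=freqs,
                   n_fraction=df["n_fraction"].to_numpy(),
                   information=df["information"].to_numpy(),
                   n_sequences=0)


def _region_slice(region: tuple[int, int], length: int) -> slice:
    lo, hi = min(region), max(region)
    return slice(position_to_index(lo, length), position_to_index(hi, length) + 1)


def build_pfm(leaders: list[LeaderSequence],
              region: tuple[int, int] = (-30, -1)) -> PositionFrequencyMatrix:
    """Tally per-position base fractions and information content over a region."""
    if not leaders:
        raise ValueError("no sequences given")
    span = max(region) - min(region) + 1
    counts = np.zeros((span, 5), dtype=np.int64)  # A C G T N
    index = {b: i for i, b in enumerate(PFM_BASES + "N")}
    for ld in leaders:
        if len(ld) < -min(region):
            raise ValueError(f"leader {ld.id!r} does not cover region {region}")
        segment = ld.sequence[_region_slice(region, len(ld))]
        for j, base in enumerate(segment):
            counts[j, index[base]] += 1
    acgt = counts[:, :4].astype(float)
    denom = acgt.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(denom > 0, acgt / denom, 0.0)
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    information = np.where(denom.ravel() > 0, 2.0 - entropy, 0.0)
    counts_df = pd.DataFrame(counts, columns=list(PFM_BASES) + ["N"])
    return PositionFrequencyMatrix(
        region=(min(region), max(region)),
        counts=counts_df,
        frequencies=pd.DataFrame(freqs, columns=list(PFM_BASES)),
        n_fraction=counts[:, 4] / len(leaders),
        information=information,
        n_sequences=len(leaders),
    )


def kmer_abundance(leaders: list[LeaderSequence], k: int = 6,
                   region: tuple[int, int] = (-30, -1)) -> pd.DataFrame:
    """Overlapping k-mer counts within a region, aggregated over sequences.

    k-mers containing N are skipped. Returns a table (kmer, count, frequency)
    ranked by descending count with lexicographic tie-break.
    """
    span = max(region) - min(region) + 1
    if k > span:
        raise ValueError(f"k={k} exceeds the region span {span}")
    counts: dict[str, int] = {}
    total = 0
    for ld in leaders:
        segment = ld.sequence[_region_slice(region, len(ld))]
        for i in range(len(segment) - k + 1):
            kmer = segment[i:i + k]
            if "N" in kmer:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
            total += 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [{"kmer": kmer, "count": c, "frequency": c / total if total else 0.0}
         for kmer, c in rows]
    )


_LOGO_COLOURS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def export_logo(pfm: PositionFrequencyMatrix, image_path: str | Path,
                matrix_path: str | Path | None = None,
                scaling: str = "information") -> None:
    """Render a sequence logo (stacked letters) and export the matrix as TSV.

    ``scaling='information'`` draws letter stacks of total height equal to
    the position's information content (classic logo convention); heights
    within a stack are proportional to base fractions. ``scaling='frequency'``
    draws stacks of height 1.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    if scaling not in ("information", "frequency"):
        raise ValueError("scaling must be 'information' or 'frequency'")
    if matrix_path is not None:
        pfm.to_tsv(matrix_path)
    positions = pfm.positions
    freqs = pfm.frequencies.to_numpy()
    fig, ax = plt.subplots(figsize=(max(len(positions) * 0.3, 4), 2.5))
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    for col, pos in enumerate(positions):
        stack_height = pfm.information[col] if scaling == "information" else 1.0
        y = 0.0
        order = np.argsort(freqs[col])  # draw smallest first, largest on top
        for bi in order:
            frac = freqs[col, bi]
            h = frac * stack_height
            if h <= 0:
                continue
            base = PFM_BASES[bi]
            tp = TextPath((0, 0), base, size=1.0, prop=fp)
            bbox = tp.get_extents()
            transform = (Affine2D()
                         .translate(-bbox.x0, -bbox.y0)
                         .scale(0.9 / bbox.width, h / bbox.height)
                         .translate(col + 0.05, y))
            ax.add_patch(PathPatch(tp.transformed(transform),
                                   facecolor=_LOGO_COLOURS[base], edgecolor="none"))
            y += h
    ax.set_xlim(0, len(positions))
    ax.set_ylim(0, 2.0 if scaling == "information" else 1.0)
    ticks = np.linspace(0, len(positions) - 1, min(len(positions), 7)).astype(int)
    ax.set_xticks(ticks + 0.5)
    ax.set_xticklabels([str(positions[t]) for t in ticks])
    ax.set_xlabel("position relative to start codon (bp)")
    ax.set_ylabel("bits" if scaling == "information" else "fraction")
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)


def pfm_weighted_average(pfms: list[PositionFrequencyMatrix]) -> np.ndarray:
    """Frequency matrix of the pooled data, from subset PFMs weighted by size."""
    weights = np.array([p.n_sequences for p in pfms], dtype=float)
    counts = sum(p.counts[list(PFM_BASES)].to_numpy() for p in pfms)
    denom = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, counts / denom, 0.0)
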