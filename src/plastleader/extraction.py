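"""Extraction of upstream leader windows from annotated chloroplast genomes.

Given a genome record and its CDS annotations, the extractor takes the fixed
window immediately 5' of each start codon on the coding strand (default
300 nt), optionally wrapping around the origin for circular plastomes.
Coordinates are 1-based inclusive internally (GenBank convention); leaders
are reported to users in the upstream -1..-L convention. The window is
deliberately not trimmed at upstream genes: a fixed 300 nt leader may well
include promoter elements, which is part of what makes it informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .sequences import LeaderSequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature; ``start``/``end`` are 1-based inclusive."""

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid CDS coordinates {self.start}..{self.end}")


@dataclass
class GenomeRecord:
    """A genome (or contig) sequence with its CDS features."""

    accession: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self):
        seq = self.sequence.upper()
        cleaned = []
        mapped = 0
        for base in seq:
            if base in "ACGTN":
                cleaned.append(base)
            else:
                cleaned.append("N")  # IUPAC ambiguity codes other than N
                mapped += 1
        if mapped:
            warnings.warn(
                f"{self.accession}: {mapped} ambiguity base(s) mapped to N",
                stacklevel=2,
            )
        self.sequence = "".join(cleaned)
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty genome sequence")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"{self.accession}: CDS {f.gene_id} ends at {f.end} "
                    f"beyond genome length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def filter_genomes(records: list[GenomeRecord], min_length: int = 5000) -> list[GenomeRecord]:
    """Keep records of at least ``min_length`` nt (boundary included), order preserved."""
    return [r for r in records if len(r) >= min_length]


def _fetch(record: GenomeRecord, lo: int, hi: int) -> str | None:
    """1-based inclusive slice [lo, hi], wrapping for circular genomes.

    Returns None when the span runs off a linear genome.
    """
    L = len(record)
    if 1 <= lo and hi <= L:
        return record.sequence[lo - 1:hi]
    if not record.circular:
        return None
    span = hi - lo + 1
    if span > L:
        return None
    return "".join(record.sequence[(i - 1) % L] for i in range(lo, hi + 1))


def extract_leader(record: GenomeRecord, cds: CdsFeature, length: int = 300,
                   label: str = "unlabelled",
                   short_policy: str = "skip") -> LeaderSequence | None:
    """Extract the ``length``-nt window 5' of ``cds`` on its coding strand.

    For '+' features this is genome positions [start-length, start-1] read
    5'->3'; for '-' features, the reverse complement of [end+1, end+length].
    Either way the returned string's final character is the base at -1.
    When fewer than ``length`` bases exist upstream (linear genome),
    ``short_policy`` decides: 'skip' returns None, 'pad' left-pads with N.
    """
    if short_policy not in ("skip", "pad"):
        raise ValueError("short_policy must be 'skip' or 'pad'")
    if cds.end > len(record):
        raise ValueError(f"CDS {cds.gene_id} lies outside {record.accession}")
    if cds.strand == "+":
        lo, hi = cds.start - length, cds.start - 1
        seq = _fetch(record, lo, hi)
        if seq is None:
            avail = cds.start - 1
            if short_policy == "skip" or avail <= 0:
                return None
            seq = "N" * (length - avail) + record.sequence[:avail]
    else:
        lo, hi = cds.end + 1, cds.end + length
        seq = _fetch(record, lo, hi)
        if seq is not None:
            seq = reverse_complement(seq)
        else:
            avail = len(record) - cds.end
            if short_policy == "skip" or avail <= 0:
                return None
            seq = "N" * (length - avail) + reverse_complement(record.sequence[cds.end:])
    return LeaderSequence(
        id=f"{record.accession}:{cds.gene_id}",
        sequence=seq,
        label=label,
        provenance={"accession": record.accession, "gene_id": cds.gene_id,
                    "strand": cds.strand},
    )


def extract_all_leaders(records: list[GenomeRecord], length: int = 300,
                        label: str = "unlabelled", min_genome_length: int = 5000,
                        short_policy: str = "skip",
                        dedup: bool = True) -> list[LeaderSequence]:
    """Filter genomes, extract a leader per CDS, and deduplicate within the label."""
    leaders = []
    for record in filter_genomes(records, min_genome_length):
        for cds in record.features:
            ld = extract_leader(record, cds, length, label, short_policy)
            if ld is not None:
                leaders.append(ld)
    return deduplicate(leaders) if dedup else leaders


def deduplicate(leaders: list[LeaderSequence]) -> list[LeaderSequence]:
    """Remove exact-duplicate sequences *within each class*, keeping the first
    occurrence; order otherwise preserved. Never collapses across classes."""
    seen: set[tuple[str, str]] = set()
    out = []
    for ld in leaders:
        key = (ld.label, ld.sequence)
        if key in seen:
            continue
        seen.add(key)
        out.append(ld)
    return out


# -- file readers ------------------------------------------------------

def _gene_id(feature, fallback: str) -> str:
    for key in ("gene", "locus_tag", "protein_id"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return fallback


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Read GenBank flat files into :class:`GenomeRecord` objects.

    For multi-segment (joined) CDS locations only the 5'-most biological
    segment is used, which is the one carrying the start codon.
    """
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        features = []
        for i, f in enumerate(rec.features):
            if f.type != "CDS" or f.location is None:
                continue
            strand = "-" if f.location.strand == -1 else "+"
            parts = sorted(f.location.parts, key=lambda p: int(p.start))
            part = parts[0] if strand == "+" else parts[-1]
            features.append(CdsFeature(
                gene_id=_gene_id(f, f"cds{i}"),
                start=int(part.start) + 1,
                end=int(part.end),
                strand=strand,
            ))
        records.append(GenomeRecord(
            accession=rec.id,
            sequence=str(rec.seq),
            features=features,
            circular=rec.annotations.get("topology", "linear") == "circular",
        ))
    return records


def read_fasta_gff(fasta_path: str | Path, gff_path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA genome plus GFF3 annotations (CDS features only).

    Multi-segment CDS sharing an ID contribute only their 5'-most biological
    segment (largest-coordinate segment on the '-' strand).
    """
    import gffutils

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gff_path), dbfn=":memory:", keep_order=True,
                            merge_strategy="create_unique", from_string=False)
    per_record: dict[str, dict[str, CdsFeature]] = {acc: {} for acc in seqs}
    for f in db.features_of_type("CDS"):
        if f.seqid not in seqs:
            continue
        gene_id = (f.attributes.get("ID", [None])[0]
                   or f.attributes.get("Parent", [None])[0]
                   or f"cds@{f.start}")
        gene_id = gene_id.split("_")[0] if gene_id.startswith("cds-") else gene_id
        strand = "-" if f.strand == "-" else "+"
        cds = CdsFeature(gene_id=gene_id, start=f.start, end=f.end, strand=strand)
        existing = per_record[f.seqid].get(gene_id)
        if existing is None:
            per_record[f.seqid][gene_id] = cds
        elif strand == "+" and cds.start < existing.start:
            per_record[f.seqid][gene_id] = cds
        elif strand == "-" and cds.end > existing.end:
            per_record[f.seqid][gene_id] = cds
    return [
        GenomeRecord(accession=acc, sequence=seq,
                     features=list(per_record[acc].values()))
        for acc, seq in seqs.items()
    ]
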