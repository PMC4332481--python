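"""Read ingestion, collapsing, length filtering and exact genome mapping.

All coordinates are 0-based half-open internally; GFF3 input (1-based,
closed) is converted at the parsing boundary.  Sequences are stored in the
DNA alphabet (U -> T on input).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to the canonical DNA alphabet."""
    return seq.strip().upper().replace("U", "T")


@dataclass
class SmallRNA:
    """A distinct 18-26 nt sequence with per-library read counts."""

    sequence: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SmallRNA({self.sequence}, n={self.total_count})"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named reference."""

    ref: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.ref != other.ref:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.ref == other.ref
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class AlignmentHit:
    """Exact full-length placement of a small RNA on a reference."""

    sequence: str
    interval: GenomicInterval


@dataclass
class TranscriptModel:
    """A transcript placed on the genome with an exon chain."""

    id: str
    gene_id: str
    interval: GenomicInterval
    exons: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons))
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if e0 > s1:
                raise ValueError(f"overlapping exons in {self.id}")
        for s, e in exons:
            if s < self.interval.start or e > self.interval.end:
                raise ValueError(f"exon outside span in {self.id}")
        self.exons = exons or ((self.interval.start, self.interval.end),)

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if e0 < s1
        )


@dataclass(frozen=True)
class RepeatFeature:
    """An annotated repeat with a hierarchical class label and sub-genome tag."""

    interval: GenomicInterval
    repeat_class: str
    subgenome: str = ""


# ---------------------------------------------------------------------------
# collapse / filter / map
# ---------------------------------------------------------------------------


def collapse_reads(libraries: Mapping[str, Iterable[str]]) -> List[SmallRNA]:
    """Collapse raw per-library sequences into distinct SmallRNAs.

    Records containing characters outside ACGTUN are rejected with a logged
    warning.  Output is deterministic: sorted lexicographically by sequence.
    """
    table: Dict[str, Dict[str, int]] = {}
    for lib_id, seqs in libraries.items():
        for raw in seqs:
            seq = normalize_sequence(raw)
            if not seq or not set(seq) <= _VALID:
                logger.warning("rejecting non-nucleotide record %r in %s", raw, lib_id)
                continue
            counts = table.setdefault(seq, {})
            counts[lib_id] = counts.get(lib_id, 0) + 1
    return [SmallRNA(seq, table[seq]) for seq in sorted(table)]


def collapse_counted(libraries: Mapping[str, Mapping[str, int]]) -> List[SmallRNA]:
    """Collapse pre-counted (sequence -> count) libraries into SmallRNAs."""
    table: Dict[str, Dict[str, int]] = {}
    for lib_id, seq_counts in libraries.items():
        for raw, count in seq_counts.items():
            seq = normalize_sequence(raw)
            if not seq or not set(seq) <= _VALID:
                logger.warning("rejecting non-nucleotide record %r in %s", raw, lib_id)
                continue
            if count < 0:
                raise ValueError(f"negative count for {seq} in {lib_id}")
            counts = table.setdefault(seq, {})
            counts[lib_id] = counts.get(lib_id, 0) + count
    return [SmallRNA(seq, table[seq]) for seq in sorted(table)]


def filter_by_length(
    srnas: Sequence[SmallRNA], min_len: int = 18, max_len: int = 26
) -> List[SmallRNA]:
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [s for s in srnas if min_len <= s.length <= max_len]


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


def map_exact(
    srnas: Sequence[SmallRNA], genome: Mapping[str, str]
) -> List[AlignmentHit]:
    """All exact full-length occurrences of each sRNA on both genome strands.

    Ns in the genome never match (an exact character comparison).  sRNAs
    containing N never match either.
    """
    hits: List[AlignmentHit] = []
    for srna in srnas:
        seq = srna.sequence
        if "N" in seq:
            continue
        rc = reverse_complement(seq)
        for ref in sorted(genome):
            ref_seq = genome[ref]
            for start in _find_all(ref_seq, seq):
                hits.append(
                    AlignmentHit(seq, GenomicInterval(ref, start, start + len(seq), "+"))
                )
            for start in _find_all(ref_seq, rc):
                hits.append(
                    AlignmentHit(seq, GenomicInterval(ref, start, start + len(seq), "-"))
                )
    return hits


def map_exact_transcript(
    srnas: Sequence[SmallRNA],
    transcripts: Mapping[str, str],
    both_strands: bool = True,
) -> List[AlignmentHit]:
    """Exact placement on transcript sequences (sense, optionally antisense)."""
    hits: List[AlignmentHit] = []
    for srna in srnas:
        seq = srna.sequence
        if "N" in seq:
            continue
        rc = reverse_complement(seq)
        for tid in sorted(transcripts):
            tseq = transcripts[tid]
            for start in _find_all(tseq, seq):
                hits.append(
                    AlignmentHit(seq, GenomicInterval(tid, start, start + len(seq), "+"))
                )
            if both_strands:
                for start in _find_all(tseq, rc):
                    hits.append(
                        AlignmentHit(
                            seq, GenomicInterval(tid, start, start + len(seq), "-")
                        )
                    )
    return hits


# ---------------------------------------------------------------------------
# file format boundaries
# ---------------------------------------------------------------------------


def read_fasta(path) -> Dict[str, str]:
    """Load a FASTA file as {id: DNA sequence}."""
    return {
        rec.id: normalize_sequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def read_reads_fasta(path, library_id: str) -> Dict[str, Mapping[str, int]]:
    """Read a collapsed-read FASTA; count parsed from a trailing "_xN" header."""
    counts: Dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        n = 1
        if "_x" in rec.id:
            suffix = rec.id.rsplit("_x", 1)[1]
            if suffix.isdigit():
                n = int(suffix)
        counts[seq] = counts.get(seq, 0) + n
    return {library_id: counts}


def read_reads_tsv(path, library_id: str) -> Dict[str, Mapping[str, int]]:
    """Read a two-column sequence<TAB>count library file."""
    counts: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            seq = normalize_sequence(parts[0])
            n = int(parts[1]) if len(parts) > 1 else 1
            counts[seq] = counts.get(seq, 0) + n
    return {library_id: counts}


def _gff3_attributes(field: str) -> Dict[str, str]:
    attrs = {}
    for item in field.strip().split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff3_transcripts(path) -> List[TranscriptModel]:
    """Parse transcript models (mRNA/transcript + exon features) from GFF3."""
    spans: Dict[str, GenomicInterval] = {}
    genes: Dict[str, str] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            ref, _, ftype, start, end, _, strand, _, attr_field = cols[:9]
            attrs = _gff3_attributes(attr_field)
            iv = GenomicInterval(ref, int(start) - 1, int(end), strand)
            if ftype in ("mRNA", "transcript", "ncRNA"):
                tid = attrs.get("ID", f"{ref}:{start}-{end}")
                spans[tid] = iv
                genes[tid] = attrs.get("Parent", attrs.get("gene_id", tid))
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent:
                    exons.setdefault(parent, []).append((iv.start, iv.end))
    return [
        TranscriptModel(tid, genes[tid], spans[tid], tuple(exons.get(tid, [])))
        for tid in sorted(spans)
    ]


def read_gff3_repeats(path) -> List[RepeatFeature]:
    """Parse repeat features from GFF3 (class in repeat_class/Name attribute)."""
    feats: List[RepeatFeature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            ref, _, _, start, end, _, strand, _, attr_field = cols[:9]
            attrs = _gff3_attributes(attr_field)
            cls = attrs.get("repeat_class", attrs.get("Name", "Others"))
            sub = attrs.get("subgenome", ref)
            strand = strand if strand in "+-" else "+"
            feats.append(
                RepeatFeature(GenomicInterval(ref, int(start) - 1, int(end), strand), cls, sub)
            )
    return feats


def read_bed_repeats(path, subgenome_of_ref: Optional[Mapping[str, str]] = None) -> List[RepeatFeature]:
    """Parse repeats from BED6 with the class label in the name column."""
    feats: List[RepeatFeature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            ref, start, end = cols[0], int(cols[1]), int(cols[2])
            cls = cols[3] if len(cols) > 3 else "Others"
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            sub = (subgenome_of_ref or {}).get(ref, ref)
            feats.append(RepeatFeature(GenomicInterval(ref, start, end, strand), cls, sub))
    return feats


def read_known_mirnas(path) -> Dict[str, str]:
    """Load a known-miRNA catalogue as {record id: mature sequence (DNA)}."""
    return read_fasta(path)
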