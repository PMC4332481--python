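"""Natural antisense transcript (NAT) pair detection and nat-siRNA profiling.

cis pairs: opposite-strand transcripts sharing >= 50 nt of the same genomic
locus, classified into four overlap orientations.  trans pairs: transcript
pairs whose sequences align complementarily over >= 100 nt and can form a
>= 50 nt duplex with >= 90% paired positions (Watson-Crick or G:U).  Duplex
assessment is alignment-based, not thermodynamic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import Align

from .sequence_io import (
    AlignmentHit,
    GenomicInterval,
    SmallRNA,
    TranscriptModel,
    reverse_complement,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_CIS_OVERLAP = 50
DEFAULT_MIN_TRANS_OVERLAP = 100
DEFAULT_MIN_DUPLEX_LEN = 50
DEFAULT_MIN_PAIRED_FRACTION = 0.9

CONVERGENT = "convergent"
DIVERGENT = "divergent"
ENCLOSED = "enclosed"
COINCIDED = "coincided"

# paired columns in an (a vs revcomp(b)) alignment: identical bases are
# Watson-Crick pairs of the original strands; (G, A) and (T, C) are G:U.
_PAIRED_COLUMNS = {
    ("A", "A"), ("C", "C"), ("G", "G"), ("T", "T"),
    ("G", "A"), ("T", "C"),
}


@dataclass
class NatPair:
    kind: str  # "cis" | "trans"
    transcript_a: str
    transcript_b: str
    overlap_length: int
    # cis geometry
    overlap: Optional[GenomicInterval] = None
    orientation: Optional[str] = None
    # trans geometry: coordinate spans on each transcript + alignment columns
    span_a: Optional[Tuple[int, int]] = None
    span_b: Optional[Tuple[int, int]] = None
    paired_fraction: Optional[float] = None
    columns: Optional[List[Tuple[str, str]]] = None

    @property
    def pair_id(self) -> str:
        return f"{self.transcript_a}|{self.transcript_b}"


@dataclass
class NatSirnaAssignment:
    sequence: str
    pair_id: str
    region: str  # overlap | non_overlap
    feature: str  # exon | intron
    strand: str  # plus | minus
    reads: int = 0


# ---------------------------------------------------------------------------
# cis
# ---------------------------------------------------------------------------


def find_cis_nats(
    transcripts: Sequence[TranscriptModel],
    min_overlap: int = DEFAULT_MIN_CIS_OVERLAP,
) -> List[NatPair]:
    """Opposite-strand transcript pairs overlapping >= min_overlap nt."""
    pairs: List[NatPair] = []
    ordered = sorted(transcripts, key=lambda t: t.id)
    for ta, tb in itertools.combinations(ordered, 2):
        ia, ib = ta.interval, tb.interval
        if ia.ref != ib.ref or ia.strand == ib.strand:
            continue
        ov = ia.overlap_length(ib)
        if ov < min_overlap:
            continue
        overlap = GenomicInterval(
            ia.ref, max(ia.start, ib.start), min(ia.end, ib.end), "+"
        )
        pair = NatPair(
            kind="cis",
            transcript_a=ta.id,
            transcript_b=tb.id,
            overlap_length=ov,
            overlap=overlap,
        )
        pair.orientation = classify_orientation(ia, ib)
        pairs.append(pair)
    return pairs


def classify_orientation(a: GenomicInterval, b: GenomicInterval) -> str:
    """Orientation of an opposite-strand overlapping pair.

    coincided: identical spans.  enclosed: one span contains the other
    (shared endpoints allowed, short of full identity).  Otherwise the pair
    overlaps partially: convergent when both 3' termini lie in the overlap,
    divergent when both 5' termini do.  The 3' terminus of a + transcript is
    its right end; of a - transcript, its left end.
    """
    if a.strand == b.strand:
        raise ValueError("orientation is defined for opposite-strand pairs")
    if (a.start, a.end) == (b.start, b.end):
        return COINCIDED
    if (a.start <= b.start and b.end <= a.end) or (b.start <= a.start and a.end <= b.end):
        return ENCLOSED
    lo, hi = max(a.start, b.start), min(a.end, b.end)

    def termini_in_overlap(iv: GenomicInterval) -> Tuple[bool, bool]:
        # (five_prime_in, three_prime_in); terminus coordinates as end points
        left_in = lo <= iv.start < hi or iv.start == lo
        right_in = lo < iv.end <= hi
        if iv.strand == "+":
            return left_in, right_in
        return right_in, left_in

    a5, a3 = termini_in_overlap(a)
    b5, b3 = termini_in_overlap(b)
    if a3 and b3:
        return CONVERGENT
    if a5 and b5:
        return DIVERGENT
    # mixed terminus pair without containment: classify by the terminus kind
    # that appears twice, preferring convergent for determinism
    return CONVERGENT if (a3 or b3) else DIVERGENT


# ---------------------------------------------------------------------------
# trans
# ---------------------------------------------------------------------------


def _complement_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -4
    return aligner


def _alignment_columns(alignment, seq_a: str, rc_b: str) -> List[Tuple[str, str]]:
    cols: List[Tuple[str, str]] = []
    blocks_a, blocks_b = alignment.aligned
    prev_a_end: Optional[int] = None
    prev_b_end: Optional[int] = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            for i in range(prev_a_end, a0):
                cols.append((seq_a[i], "-"))
            for j in range(prev_b_end, b0):
                cols.append(("-", rc_b[j]))
        cols.extend((seq_a[i], rc_b[j]) for i, j in zip(range(a0, a1), range(b0, b1)))
        prev_a_end, prev_b_end = a1, b1
    return cols


def find_trans_nats(
    sequences: Mapping[str, str],
    exclude: Set[str] = frozenset(),
    min_overlap: int = DEFAULT_MIN_TRANS_OVERLAP,
) -> List[NatPair]:
    """All-vs-all complementarity search (local alignment vs revcomp)."""
    aligner = _complement_aligner()
    ids = [t for t in sorted(sequences) if t not in exclude]
    pairs: List[NatPair] = []
    for ta, tb in itertools.combinations(ids, 2):
        seq_a, seq_b = sequences[ta], sequences[tb]
        rc_b = reverse_complement(seq_b)
        alignments = aligner.align(seq_a, rc_b)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        blocks_a, blocks_b = aln.aligned
        if len(blocks_a) == 0:
            continue
        a0, a1 = int(blocks_a[0][0]), int(blocks_a[-1][1])
        b0, b1 = int(blocks_b[0][0]), int(blocks_b[-1][1])
        if a1 - a0 < min_overlap or b1 - b0 < min_overlap:
            continue
        # convert revcomp coordinates back to transcript-b coordinates
        span_b = (len(seq_b) - b1, len(seq_b) - b0)
        pairs.append(
            NatPair(
                kind="trans",
                transcript_a=ta,
                transcript_b=tb,
                overlap_length=min(a1 - a0, b1 - b0),
                span_a=(a0, a1),
                span_b=span_b,
                columns=_alignment_columns(aln, seq_a, rc_b),
            )
        )
    return pairs


def duplex_filter(
    pair: NatPair,
    min_duplex_len: int = DEFAULT_MIN_DUPLEX_LEN,
    min_paired_fraction: float = DEFAULT_MIN_PAIRED_FRACTION,
) -> Tuple[float, bool]:
    """Best-window paired fraction and acceptance of a trans candidate.

    Accepted iff some alignment window of >= min_duplex_len columns has a
    paired fraction >= min_paired_fraction; paired = Watson-Crick or G:U.
    Returns (best qualifying fraction, accepted); when no window qualifies,
    the best fraction over windows of exactly min_duplex_len is reported.
    """
    if not pair.columns:
        return 0.0, False
    paired = np.array(
        [1 if col in _PAIRED_COLUMNS else 0 for col in pair.columns], dtype=np.int64
    )
    L = len(paired)
    if L < min_duplex_len:
        return 0.0, False
    prefix = np.concatenate([[0], np.cumsum(paired)])
    best_fraction = 0.0
    accepted = False
    for w in range(min_duplex_len, L + 1):
        sums = prefix[w:] - prefix[:-w]
        frac = float(sums.max()) / w
        if frac >= min_paired_fraction - 1e-12:
            accepted = True
            best_fraction = max(best_fraction, frac)
        elif not accepted:
            best_fraction = max(best_fraction, frac)
    pair.paired_fraction = best_fraction
    return best_fraction, accepted


def duplex_filter_sequences(
    seq_a: str,
    seq_b: str,
    min_duplex_len: int = DEFAULT_MIN_DUPLEX_LEN,
    min_paired_fraction: float = DEFAULT_MIN_PAIRED_FRACTION,
) -> Tuple[float, bool]:
    """Convenience wrapper: align two sequences, then apply duplex_filter."""
    pairs = find_trans_nats({"a": seq_a, "b": seq_b}, min_overlap=1)
    if not pairs:
        return 0.0, False
    return duplex_filter(pairs[0], min_duplex_len, min_paired_fraction)


# ---------------------------------------------------------------------------
# nat-siRNA assignment and enrichment
# ---------------------------------------------------------------------------


def _midpoint(hit: AlignmentHit) -> int:
    return (hit.interval.start + hit.interval.end) // 2


def assign_nat_sirnas(
    hits: Sequence[AlignmentHit],
    pairs: Sequence[NatPair],
    transcripts: Mapping[str, TranscriptModel],
    counts: Mapping[str, int],
) -> List[NatSirnaAssignment]:
    """Label cis-pair hits by region/feature/strand (midpoint rule).

    ``hits`` are genomic; a hit belongs to a pair when its midpoint falls in
    either member span.  region = overlap iff the midpoint is inside the
    pair's overlap interval; feature = exon iff the midpoint lies in an exon
    of an overlapped member transcript.
    """
    out: List[NatSirnaAssignment] = []
    for pair in pairs:
        if pair.kind != "cis":
            continue
        ta = transcripts[pair.transcript_a]
        tb = transcripts[pair.transcript_b]
        for hit in hits:
            mid = _midpoint(hit)
            if hit.interval.ref != ta.interval.ref:
                continue
            members = [
                t
                for t in (ta, tb)
                if t.interval.start <= mid < t.interval.end
            ]
            if not members:
                continue
            region = (
                "overlap"
                if pair.overlap.start <= mid < pair.overlap.end
                else "non_overlap"
            )
            feature = "intron"
            for t in members:
                if any(s <= mid < e for s, e in t.exons):
                    feature = "exon"
                    break
            out.append(
                NatSirnaAssignment(
                    sequence=hit.sequence,
                    pair_id=pair.pair_id,
                    region=region,
                    feature=feature,
                    strand="plus" if hit.interval.strand == "+" else "minus",
                    reads=counts.get(hit.sequence, 0),
                )
            )
    return out


def assign_trans_nat_sirnas(
    hits: Sequence[AlignmentHit],
    pairs: Sequence[NatPair],
    counts: Mapping[str, int],
) -> List[NatSirnaAssignment]:
    """Label transcript-coordinate hits against trans-pair aligned spans."""
    spans: Dict[str, List[Tuple[str, Tuple[int, int]]]] = {}
    for pair in pairs:
        if pair.kind != "trans":
            continue
        spans.setdefault(pair.transcript_a, []).append((pair.pair_id, pair.span_a))
        spans.setdefault(pair.transcript_b, []).append((pair.pair_id, pair.span_b))
    out: List[NatSirnaAssignment] = []
    for hit in hits:
        for pair_id, (s, e) in spans.get(hit.interval.ref, ()):
            mid = _midpoint(hit)
            region = "overlap" if s <= mid < e else "non_overlap"
            out.append(
                NatSirnaAssignment(
                    sequence=hit.sequence,
                    pair_id=pair_id,
                    region=region,
                    feature="exon",
                    strand="plus" if hit.interval.strand == "+" else "minus",
                    reads=counts.get(hit.sequence, 0),
                )
            )
    return out


def enrichment_profile(assignments: Sequence[NatSirnaAssignment]) -> pd.DataFrame:
    """Read fractions by region, feature and strand (each dichotomy sums to 1)."""
    if not assignments:
        return pd.DataFrame(columns=["dimension", "key", "reads", "fraction"])
    rows = []
    total = sum(a.reads for a in assignments)
    for dim, keys in (
        ("region", ("overlap", "non_overlap")),
        ("feature", ("exon", "intron")),
        ("strand", ("plus", "minus")),
    ):
        for key in keys:
            reads = sum(a.reads for a in assignments if getattr(a, dim) == key)
            rows.append(
                {
                    "dimension": dim,
                    "key": key,
                    "reads": reads,
                    "fraction": reads / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)
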