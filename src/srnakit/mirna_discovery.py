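"""miRNA locus discovery from genome-mapped small RNAs.

Candidate reads are pre-filtered by
abundance and genomic copy number, grouped into loci, screened by strand and
abundance bias, and the mature/star duplex is validated on a folded
precursor with 2-nt 3' overhang geometry and at most four duplex mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .fold import FoldFunction, nussinov_fold, pairing_partners
from .sequence_io import (
    AlignmentHit,
    GenomicInterval,
    SmallRNA,
    reverse_complement,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL = 10
DEFAULT_MAX_GENOME_HITS = 5000
DEFAULT_MAX_GAP = 200
DEFAULT_MAX_DISTANCE = 450
DEFAULT_SHIFT_TOLERANCE = 3
DEFAULT_MIN_STRAND_BIAS = 0.8
DEFAULT_MIN_ABUNDANCE_BIAS = 0.6
DEFAULT_MAX_DUPLEX_MISMATCHES = 4
DEFAULT_FLANK = 20


@dataclass
class SrnaCluster:
    """A strandless span of hits separated by at most ``max_gap`` nt."""

    interval: GenomicInterval
    hits: List[AlignmentHit] = field(default_factory=list)


@dataclass
class MirnaLocus:
    """An accepted miRNA precursor with its mature/star duplex evidence."""

    precursor: GenomicInterval
    precursor_sequence: str
    mature: SmallRNA
    mature_offset: int
    star: SmallRNA
    star_offset: int
    strand_bias: float
    abundance_bias: float
    duplex_mismatches: int
    structure: str
    source: str = "genome"

    @property
    def mature_interval(self) -> GenomicInterval:
        return self._sub_interval(self.mature_offset, self.mature.length)

    @property
    def star_interval(self) -> GenomicInterval:
        return self._sub_interval(self.star_offset, self.star.length)

    def _sub_interval(self, offset: int, length: int) -> GenomicInterval:
        p = self.precursor
        if p.strand == "+":
            start = p.start + offset
        else:
            start = p.end - offset - length
        return GenomicInterval(p.ref, start, start + length, p.strand)


def cluster_hits(hits: Sequence[AlignmentHit], max_gap: int = DEFAULT_MAX_GAP) -> List[SrnaCluster]:
    """Group hits into maximal clusters with adjacent gaps <= max_gap."""
    clusters: List[SrnaCluster] = []
    ordered = sorted(hits, key=lambda h: (h.interval.ref, h.interval.start, h.interval.end))
    current: List[AlignmentHit] = []
    cur_ref, cur_end = None, None
    for hit in ordered:
        iv = hit.interval
        if current and iv.ref == cur_ref and iv.start - cur_end <= max_gap:
            current.append(hit)
            cur_end = max(cur_end, iv.end)
        else:
            if current:
                clusters.append(_finalize_cluster(current))
            current = [hit]
            cur_ref, cur_end = iv.ref, iv.end
    if current:
        clusters.append(_finalize_cluster(current))
    return clusters


def _finalize_cluster(hits: List[AlignmentHit]) -> SrnaCluster:
    start = min(h.interval.start for h in hits)
    end = max(h.interval.end for h in hits)
    return SrnaCluster(GenomicInterval(hits[0].interval.ref, start, end, "+"), hits)


def candidate_filter(
    srnas: Sequence[SmallRNA],
    genome_hit_counts: Mapping[str, int],
    min_total: int = DEFAULT_MIN_TOTAL,
    max_genome_hits: int = DEFAULT_MAX_GENOME_HITS,
) -> List[SmallRNA]:
    """Abundance (>= min_total reads) and copy-number (<= max hits) pre-filter."""
    return [
        s
        for s in srnas
        if s.total_count >= min_total
        and 0 < genome_hit_counts.get(s.sequence, 0) <= max_genome_hits
    ]


def _cluster_srna_counts(
    cluster: SrnaCluster, counts: Mapping[str, int]
) -> Dict[str, int]:
    """Reads contributed per distinct sequence, full counts at every hit."""
    tally: Dict[str, int] = {}
    for hit in cluster.hits:
        tally[hit.sequence] = tally.get(hit.sequence, 0) + counts[hit.sequence]
    return tally


def _most_abundant(tally: Mapping[str, int]) -> str:
    # tie-break: lexicographically smallest sequence, for determinism
    return min(tally, key=lambda s: (-tally[s], s))


def locus_biases(
    cluster: SrnaCluster, counts: Mapping[str, int]
) -> Tuple[float, float]:
    """(strand_bias, abundance_bias) of a cluster.

    Sense strand is the strand of the most abundant sRNA.  strand_bias =
    sense reads / total reads; abundance_bias = reads of the top-3 distinct
    sRNAs / total reads.
    """
    if not cluster.hits:
        raise ValueError("empty cluster")
    per_hit = [(h, counts[h.sequence]) for h in cluster.hits]
    total = sum(c for _, c in per_hit)
    if total == 0:
        raise ValueError("cluster with zero total reads")
    tally = _cluster_srna_counts(cluster, counts)
    top = _most_abundant(tally)
    sense_strand = next(
        h.interval.strand
        for h in sorted(cluster.hits, key=lambda h: (h.interval.start, h.interval.strand))
        if h.sequence == top
    )
    sense = sum(c for h, c in per_hit if h.interval.strand == sense_strand)
    top3 = sum(sorted(tally.values(), reverse=True)[:3])
    return sense / total, top3 / total


def validate_hairpin(
    precursor_sequence: str,
    mature_offset: int,
    mature_length: int,
    star_offset: int,
    star_length: int,
    fold_fn: FoldFunction = nussinov_fold,
    max_mismatches: int = DEFAULT_MAX_DUPLEX_MISMATCHES,
    overhang: int = 2,
) -> Tuple[str, int, bool]:
    """Fold a precursor and count mature/star duplex mismatches.

    A mismatch is a position in one arm that is not paired to a position in
    the other arm (bulges and loops included); the reported count is the
    maximum over the two arms.  The canonical 2-nt 3' overhang of each read
    (its last ``overhang`` positions in precursor orientation) is expected
    to be unpaired and never counted, so a perfect duplex scores 0.
    Accepted iff <= max_mismatches and the two reads sit on opposite arms
    of a stem (at least one cross pairing, no pairing within either read).
    """
    structure = fold_fn(precursor_sequence)
    if len(structure) != len(precursor_sequence):
        raise ValueError("fold function returned structure of wrong length")
    partners = pairing_partners(structure)
    m_span = range(mature_offset, mature_offset + mature_length)
    s_span = range(star_offset, star_offset + star_length)
    s_set = set(s_span)
    m_set = set(m_span)

    cross = 0
    internal = 0
    m_mismatch = 0
    for i in m_span:
        p = partners[i]
        if p is None or p not in s_set:
            if i < mature_offset + mature_length - overhang:
                m_mismatch += 1
            if p is not None and p in m_set:
                internal += 1
        else:
            cross += 1
    s_mismatch = 0
    for i in s_span:
        p = partners[i]
        if (p is None or p not in m_set) and i < star_offset + star_length - overhang:
            s_mismatch += 1
    mismatches = max(m_mismatch, s_mismatch)
    accepted = cross > 0 and internal == 0 and mismatches <= max_mismatches
    return structure, mismatches, accepted


def find_duplex_pairs(
    cluster: SrnaCluster,
    counts: Mapping[str, int],
    genome: Mapping[str, str],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    shift_tolerance: int = DEFAULT_SHIFT_TOLERANCE,
    flank: int = DEFAULT_FLANK,
    fold_fn: FoldFunction = nussinov_fold,
    max_mismatches: int = DEFAULT_MAX_DUPLEX_MISMATCHES,
) -> List[MirnaLocus]:
    """Candidate (mature, star) duplexes for a cluster.

    The mature is the most abundant sRNA; star candidates are same-strand
    sRNAs within max_distance whose 5' start is consistent with the folded
    duplex position (2-nt 3' overhangs) within +/- shift_tolerance nt.
    Returns accepted loci sorted best-first (fewest mismatches, most star
    reads).
    """
    tally = _cluster_srna_counts(cluster, counts)
    if not tally:
        return []
    mature_seq = _most_abundant(tally)
    mature_hits = [h for h in cluster.hits if h.sequence == mature_seq]
    loci: List[MirnaLocus] = []
    seen = set()
    for m_hit in mature_hits:
        strand = m_hit.interval.strand
        for s_hit in cluster.hits:
            if s_hit.interval.strand != strand or s_hit.sequence == mature_seq:
                continue
            if abs(s_hit.interval.start - m_hit.interval.start) > max_distance:
                continue
            key = (m_hit.interval, s_hit.interval)
            if key in seen:
                continue
            seen.add(key)
            locus = _evaluate_duplex(
                m_hit,
                s_hit,
                counts,
                genome,
                flank,
                fold_fn,
                shift_tolerance,
                max_mismatches,
            )
            if locus is not None:
                loci.append(locus)
    loci.sort(key=lambda l: (l.duplex_mismatches, -counts[l.star.sequence], l.star.sequence))
    return loci


def _evaluate_duplex(
    m_hit: AlignmentHit,
    s_hit: AlignmentHit,
    counts: Mapping[str, int],
    genome: Mapping[str, str],
    flank: int,
    fold_fn: FoldFunction,
    shift_tolerance: int,
    max_mismatches: int,
) -> Optional[MirnaLocus]:
    ref_seq = genome[m_hit.interval.ref]
    lo = max(0, min(m_hit.interval.start, s_hit.interval.start) - flank)
    hi = min(len(ref_seq), max(m_hit.interval.end, s_hit.interval.end) + flank)
    strand = m_hit.interval.strand
    precursor = GenomicInterval(m_hit.interval.ref, lo, hi, strand)
    seq = ref_seq[lo:hi]
    if strand == "+":
        m_off = m_hit.interval.start - lo
        s_off = s_hit.interval.start - lo
    else:
        seq = reverse_complement(seq)
        m_off = hi - m_hit.interval.end
        s_off = hi - s_hit.interval.end
    m_len = m_hit.interval.length
    s_len = s_hit.interval.length

    structure, mismatches, accepted = validate_hairpin(
        seq, m_off, m_len, s_off, s_len, fold_fn, max_mismatches
    )
    if not accepted:
        return None
    if not _overhang_consistent(structure, m_off, m_len, s_off, s_len, shift_tolerance):
        return None
    return MirnaLocus(
        precursor=precursor,
        precursor_sequence=seq,
        mature=SmallRNA(m_hit.sequence, {"total": counts[m_hit.sequence]}),
        mature_offset=m_off,
        star=SmallRNA(s_hit.sequence, {"total": counts[s_hit.sequence]}),
        star_offset=s_off,
        strand_bias=0.0,
        abundance_bias=0.0,
        duplex_mismatches=mismatches,
        structure=structure,
    )


def _overhang_consistent(
    structure: str,
    m_off: int,
    m_len: int,
    s_off: int,
    s_len: int,
    shift_tolerance: int,
) -> bool:
    """Check the star position against the fold-predicted duplex register.

    In a canonical duplex with 2-nt 3' overhangs, a mature position at read
    index im pairs the star position at read index (m_len - 3) - im.  Every
    mature->star pairing therefore implies a register shift
    (im + is) - (m_len - 3); the star is positionally consistent when the
    median implied shift over all such pairings is within shift_tolerance.
    """
    partners = pairing_partners(structure)
    shifts = []
    for i in range(m_off, m_off + m_len):
        p = partners[i]
        if p is not None and s_off <= p < s_off + s_len:
            shifts.append((i - m_off) + (p - s_off) - (m_len - 3))
    if not shifts:
        return False
    shifts.sort()
    median = shifts[len(shifts) // 2]
    return abs(median) <= shift_tolerance


def discover_mirna_loci(
    srnas: Sequence[SmallRNA],
    genome: Mapping[str, str],
    min_total: int = DEFAULT_MIN_TOTAL,
    max_genome_hits: int = DEFAULT_MAX_GENOME_HITS,
    max_gap: int = DEFAULT_MAX_GAP,
    min_strand_bias: float = DEFAULT_MIN_STRAND_BIAS,
    min_abundance_bias: float = DEFAULT_MIN_ABUNDANCE_BIAS,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    shift_tolerance: int = DEFAULT_SHIFT_TOLERANCE,
    max_mismatches: int = DEFAULT_MAX_DUPLEX_MISMATCHES,
    flank: int = DEFAULT_FLANK,
    fold_fn: FoldFunction = nussinov_fold,
    source: str = "genome",
    precomputed_hits: Optional[Sequence[AlignmentHit]] = None,
) -> List[MirnaLocus]:
    """Full discovery stage: filter, cluster, bias-screen, duplex-validate.

    The abundance/copy-number pre-filter gates which sRNAs may seed a locus
    (the mature must be a surviving candidate); all mapped sRNAs still
    participate in clustering, bias computation and the star search, since
    star reads are routinely below the abundance cutoff.
    """
    from .sequence_io import map_exact

    hits = list(precomputed_hits) if precomputed_hits is not None else map_exact(srnas, genome)
    hit_counts: Dict[str, int] = {}
    for h in hits:
        hit_counts[h.sequence] = hit_counts.get(h.sequence, 0) + 1
    candidates = candidate_filter(srnas, hit_counts, min_total, max_genome_hits)
    cand_seqs = {s.sequence for s in candidates}
    counts = {s.sequence: s.total_count for s in srnas}
    loci: List[MirnaLocus] = []
    for cluster in cluster_hits(hits, max_gap):
        tally = _cluster_srna_counts(cluster, counts)
        if not tally or _most_abundant(tally) not in cand_seqs:
            continue
        try:
            sb, ab = locus_biases(cluster, counts)
        except ValueError:
            continue
        if sb < min_strand_bias or ab < min_abundance_bias:
            continue
        pairs = find_duplex_pairs(
            cluster,
            counts,
            genome,
            max_distance,
            shift_tolerance,
            flank,
            fold_fn,
            max_mismatches,
        )
        if not pairs:
            continue
        best = pairs[0]
        best.strand_bias = sb
        best.abundance_bias = ab
        best.source = source
        assert best.strand_bias >= min_strand_bias
        assert best.abundance_bias >= min_abundance_bias
        assert best.duplex_mismatches <= max_mismatches
        assert abs(best.mature_interval.start - best.star_interval.start) <= max_distance
        loci.append(best)
    return loci


def loci_to_gff3(loci: Sequence[MirnaLocus]) -> str:
    """Serialize loci as GFF3 precursor/mature/star features."""
    lines = ["##gff-version 3"]
    for idx, locus in enumerate(loci, start=1):
        lid = f"MIR{idx:04d}"
        p = locus.precursor
        lines.append(
            "\t".join(
                [
                    p.ref, "srnakit", "miRNA_primary_transcript",
                    str(p.start + 1), str(p.end), ".", p.strand, ".",
                    f"ID={lid};mismatches={locus.duplex_mismatches}",
                ]
            )
        )
        for tag, iv in (("miRNA", locus.mature_interval), ("miRNA_star", locus.star_interval)):
            lines.append(
                "\t".join(
                    [
                        iv.ref, "srnakit", tag,
                        str(iv.start + 1), str(iv.end), ".", iv.strand, ".",
                        f"ID={lid}.{tag};Parent={lid}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"
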