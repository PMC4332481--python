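"""Conservation split, family assignment and precursor gene context."""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from .sequence_io import GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_MAX_SUBSTITUTIONS = 3
DEFAULT_MIN_IDENTITY = 96.0
DEFAULT_MAX_MISMATCHES = 3
DEFAULT_MAX_DISTANCE = 5000

CONSERVED = "conserved"
LINEAGE_SPECIFIC = "lineage_specific"


@dataclass
class MirnaFamilyAssignment:
    mature_id: str
    conservation: str
    family: str
    best_match: Optional[str] = None
    substitutions: Optional[int] = None


@dataclass
class GeneContext:
    locus_id: str
    transcript_id: str
    context: str  # intron | exon | junction | intron_exon


@dataclass
class TranscriptAlignmentStats:
    """Precomputed transcript-to-genome alignment quality for association."""

    transcript_id: str
    identity: float
    mismatches: int
    indels: int
    distance_nt: int


def substitution_distance(a: str, b: str) -> int:
    """Best ungapped sliding-alignment distance between two sequences.

    Each overhanging nucleotide (position of either sequence outside the
    overlap) counts as one substitution; within the overlap, plain Hamming.
    """
    if not a or not b:
        return max(len(a), len(b))
    best = len(a) + len(b)
    for shift in range(-(len(b) - 1), len(a)):
        lo_a = max(0, shift)
        hi_a = min(len(a), shift + len(b))
        if hi_a <= lo_a:
            continue
        overlap = hi_a - lo_a
        hamming = sum(
            1 for i in range(lo_a, hi_a) if a[i] != b[i - shift]
        )
        overhang = (len(a) - overlap) + (len(b) - overlap)
        best = min(best, hamming + overhang)
    return best


def parse_family(name: str) -> str:
    """Family label from a known-miRNA id, e.g. "gma-miR156a-5p" -> miR156."""
    m = re.search(r"(miR[0-9]+)", name, flags=re.IGNORECASE)
    if m:
        return "miR" + m.group(1)[3:]
    return name


def classify_conservation(
    mature_id: str,
    mature_seq: str,
    known_set: Mapping[str, str],
    max_subs: int = DEFAULT_MAX_SUBSTITUTIONS,
) -> MirnaFamilyAssignment:
    """Conserved iff within max_subs substitutions of some known miRNA."""
    if not known_set:
        logger.warning("empty known-miRNA set: everything is lineage-specific")
        return MirnaFamilyAssignment(mature_id, LINEAGE_SPECIFIC, "", None, None)
    best_name, best_dist = None, None
    for name in sorted(known_set):
        d = substitution_distance(mature_seq, known_set[name])
        if best_dist is None or d < best_dist or (d == best_dist and name < best_name):
            best_name, best_dist = name, d
    if best_dist <= max_subs:
        return MirnaFamilyAssignment(
            mature_id, CONSERVED, parse_family(best_name), best_name, best_dist
        )
    return MirnaFamilyAssignment(mature_id, LINEAGE_SPECIFIC, "", best_name, best_dist)


def assign_families(
    matures: Mapping[str, str],
    known_set: Mapping[str, str],
    max_subs: int = DEFAULT_MAX_SUBSTITUTIONS,
) -> Dict[str, MirnaFamilyAssignment]:
    """Classify every mature and group lineage-specific ones into families.

    Conserved matures inherit the matched known family; lineage-specific
    matures are single-linkage clustered at <= max_subs substitutions and
    numbered miRLS-0001, ... in lexicographic order of each family's
    smallest member sequence.
    """
    assignments = {
        mid: classify_conservation(mid, seq, known_set, max_subs)
        for mid, seq in matures.items()
    }
    ls_ids = sorted(m for m, a in assignments.items() if a.conservation == LINEAGE_SPECIFIC)
    parent = {m: m for m in ls_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m1, m2 in itertools.combinations(ls_ids, 2):
        if substitution_distance(matures[m1], matures[m2]) <= max_subs:
            parent[find(m1)] = find(m2)

    groups: Dict[str, List[str]] = {}
    for m in ls_ids:
        groups.setdefault(find(m), []).append(m)
    ordered = sorted(groups.values(), key=lambda ms: min(matures[m] for m in ms))
    for idx, members in enumerate(ordered, start=1):
        label = f"miRLS-{idx:04d}"
        for m in members:
            assignments[m].family = label
    return assignments


def _position_context(iv: GenomicInterval, tx: TranscriptModel) -> Optional[str]:
    """intron / exon / junction for a precursor against one transcript."""
    if not tx.interval.contains(iv):
        return None
    for s, e in tx.exons:
        if s <= iv.start and iv.end <= e:
            return "exon"
    for s, e in tx.introns:
        if s <= iv.start and iv.end <= e:
            return "intron"
    return "junction"


def classify_gene_context(
    locus_id: str,
    precursor: GenomicInterval,
    transcripts: Sequence[TranscriptModel],
    alignment_stats: Optional[Mapping[str, TranscriptAlignmentStats]] = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> List[GeneContext]:
    """Gene context of a precursor against associated transcripts.

    When alignment statistics are supplied, only transcripts passing the
    association filter (identity >= 96%, <= 3 mismatches, no indel, within
    5000 nt) are considered.  If one associated transcript yields intron and
    another exon at the same locus, an extra merged intron_exon context is
    reported (an alternative-splicing candidate).
    """
    contexts: List[GeneContext] = []
    for tx in transcripts:
        if alignment_stats is not None:
            stats = alignment_stats.get(tx.id)
            if stats is None:
                continue
            if (
                stats.identity < min_identity
                or stats.mismatches > max_mismatches
                or stats.indels > 0
                or stats.distance_nt > max_distance
            ):
                continue
        ctx = _position_context(precursor, tx)
        if ctx is not None:
            contexts.append(GeneContext(locus_id, tx.id, ctx))
    kinds = {c.context for c in contexts}
    if "intron" in kinds and "exon" in kinds:
        tids = ",".join(sorted(c.transcript_id for c in contexts if c.context in ("intron", "exon")))
        contexts.append(GeneContext(locus_id, tids, "intron_exon"))
    return contexts


def origin_sharing(
    family_sources: Mapping[str, FrozenSet[str]],
    universe: Sequence[str] = ("A2", "D5", "transcripts"),
) -> Dict[FrozenSet[str], int]:
    """Venn cell counts: families per non-empty subset of origins."""
    cells: Dict[FrozenSet[str], int] = {}
    for r in range(1, len(universe) + 1):
        for combo in itertools.combinations(sorted(universe), r):
            cells[frozenset(combo)] = 0
    for fam in sorted(family_sources):
        sources = frozenset(family_sources[fam]) & frozenset(universe)
        if sources:
            cells[sources] += 1
    return cells
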