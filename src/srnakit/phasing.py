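"""Phased siRNA detection on transcripts.

The phasing statistic is the hypergeometric upper tail of in-register
occupancy: within a window of N = L*m candidate positions (phase length L,
m cycles) holding n distinct occupied positions, of which k fall in the
L-periodic register of the window anchor,

    p = sum_{j=k}^{min(n, m)} C(m, j) * C(N-m, n-j) / C(N, n)

computed in exact integer arithmetic.  Loci passing p < 1e-3 are then
post-filtered: >= 2 distinct phased siRNAs, at least one phased siRNA with
>= 5 reads, and in-register reads / window reads >= 0.6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .sequence_io import SmallRNA, map_exact_transcript

logger = logging.getLogger(__name__)

PHASE_LENGTH = 21
DEFAULT_CYCLES = 11
DEFAULT_MAX_PVALUE = 1e-3
DEFAULT_MIN_PHASED_SRNAS = 2
DEFAULT_MIN_MAX_READS = 5
DEFAULT_MIN_PHASED_RATIO = 0.6
ANTISENSE_SHIFT = 2

DEFAULT_SCORING_LENGTH = 18
DEFAULT_MAX_EXPECTATION = 4.0
DEFAULT_FLANK = 148
DEFAULT_MAX_SHIFT = 1

_SEED_START, _SEED_END = 2, 13  # 1-based miRNA positions with doubled penalty
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
INDEL_PENALTY = 2.0

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # miRNA base, target base (DNA alphabet)


@dataclass
class PhasingWindow:
    transcript_id: str
    anchor: int
    phase_length: int
    cycles: int
    n_positions: int  # N = phase_length * cycles
    occupied: int  # n
    in_register: int  # k
    p_value: float


@dataclass
class InitiatorCall:
    mirna_id: str
    locus_id: str
    site_start: int
    site_end: int
    expectation: float
    cleavage_position: int
    register_shift: int


@dataclass
class PhasedLocus:
    transcript_id: str
    window: PhasingWindow
    start: int
    end: int
    pha_sirnas: List[Tuple[str, int]] = field(default_factory=list)  # (sequence, position)
    max_pha_reads: int = 0
    phased_ratio: float = 0.0
    trigger: Optional[InitiatorCall] = None

    @property
    def locus_id(self) -> str:
        return f"{self.transcript_id}:{self.window.anchor}"


def phase_register_counts(
    positions: Sequence[int],
    anchor: int,
    cycles: int,
    phase_length: int = PHASE_LENGTH,
) -> Tuple[int, int, int]:
    """(N, n, k) for the window [anchor, anchor + phase_length*cycles)."""
    if cycles < 2:
        raise ValueError("cycles must be >= 2")
    N = phase_length * cycles
    window = {p for p in positions if anchor <= p < anchor + N}
    n = len(window)
    k = sum(1 for p in window if (p - anchor) % phase_length == 0)
    return N, n, k


def phasing_pvalue(N: int, n: int, k_obs: int, phase_length: int = PHASE_LENGTH) -> float:
    """Exact hypergeometric upper-tail probability of in-register occupancy."""
    if N % phase_length != 0:
        raise ValueError(f"N={N} is not a multiple of phase length {phase_length}")
    m = N // phase_length
    if not 0 <= n <= N:
        raise ValueError(f"n={n} outside [0, {N}]")
    if k_obs < 0 or k_obs > min(n, m):
        raise ValueError(f"k_obs={k_obs} outside [0, min(n, m)={min(n, m)}]")
    numerator = sum(comb(m, j) * comb(N - m, n - j) for j in range(k_obs, min(n, m) + 1))
    return float(Fraction(numerator, comb(N, n)))


def _registration_positions(hits, transcript_id: str, antisense_shift: int = ANTISENSE_SHIFT):
    """5'-start registration positions of hits on one transcript.

    Antisense hits are shifted +antisense_shift nt so that the 2-nt 3'
    overhang geometry of DCL products puts both strands in one register.
    """
    positions: Dict[int, Dict[str, int]] = {}
    for h in hits:
        if h.interval.ref != transcript_id:
            continue
        pos = h.interval.start
        if h.interval.strand == "-":
            pos += antisense_shift
        positions.setdefault(pos, {})
    return positions


def call_pyts(
    transcripts: Mapping[str, str],
    srnas: Sequence[SmallRNA],
    exclude: Set[str] = frozenset(),
    cycles: int = DEFAULT_CYCLES,
    phase_length: int = PHASE_LENGTH,
    max_pvalue: float = DEFAULT_MAX_PVALUE,
    min_phased_srnas: int = DEFAULT_MIN_PHASED_SRNAS,
    min_max_reads: int = DEFAULT_MIN_MAX_READS,
    min_phased_ratio: float = DEFAULT_MIN_PHASED_RATIO,
    both_strands: bool = True,
    antisense_shift: int = ANTISENSE_SHIFT,
) -> List[PhasedLocus]:
    """Scan every transcript for phased siRNA loci.

    Windows of ``cycles`` phase cycles are anchored at each occupied
    position; significant windows (p < max_pvalue) on a transcript are
    merged when they overlap, keeping the minimal-p window, and the merged
    locus is post-filtered by the three read-level criteria.
    """
    counts = {s.sequence: s.total_count for s in srnas if s.sequence not in exclude}
    kept = [s for s in srnas if s.sequence not in exclude]
    hits = map_exact_transcript(kept, transcripts, both_strands=both_strands)

    loci: List[PhasedLocus] = []
    for tid in sorted(transcripts):
        t_hits = [h for h in hits if h.interval.ref == tid]
        if not t_hits:
            continue
        pos_reads: Dict[int, int] = {}
        pos_seqs: Dict[int, List[str]] = {}
        for h in t_hits:
            pos = h.interval.start
            if h.interval.strand == "-":
                pos += antisense_shift
            pos_reads[pos] = pos_reads.get(pos, 0) + counts[h.sequence]
            pos_seqs.setdefault(pos, []).append(h.sequence)
        occupied = sorted(pos_reads)

        windows: List[PhasingWindow] = []
        for anchor in occupied:
            N, n, k = phase_register_counts(occupied, anchor, cycles, phase_length)
            if n == 0 or k == 0:
                continue
            p = phasing_pvalue(N, n, k, phase_length)
            if p < max_pvalue:
                windows.append(
                    PhasingWindow(tid, anchor, phase_length, cycles, N, n, k, p)
                )
        if not windows:
            continue

        # merge overlapping significant windows, keep minimal-p representative
        windows.sort(key=lambda w: w.anchor)
        merged: List[List[PhasingWindow]] = [[windows[0]]]
        for w in windows[1:]:
            last = merged[-1]
            span_end = max(x.anchor + x.n_positions for x in last)
            if w.anchor < span_end:
                last.append(w)
            else:
                merged.append([w])

        for group in merged:
            best = min(group, key=lambda w: (w.p_value, w.anchor))
            start = min(w.anchor for w in group)
            end = max(w.anchor + w.n_positions for w in group)
            locus = _build_locus(
                tid, best, start, end, pos_reads, pos_seqs, phase_length
            )
            if (
                len(locus.pha_sirnas) >= min_phased_srnas
                and locus.max_pha_reads >= min_max_reads
                and locus.phased_ratio >= min_phased_ratio
            ):
                loci.append(locus)
    return loci


def _build_locus(
    tid: str,
    window: PhasingWindow,
    start: int,
    end: int,
    pos_reads: Mapping[int, int],
    pos_seqs: Mapping[int, List[str]],
    phase_length: int,
) -> PhasedLocus:
    in_register: List[Tuple[str, int]] = []
    reg_reads = 0
    total_reads = 0
    max_reads = 0
    for pos in sorted(pos_reads):
        if not start <= pos < end:
            continue
        total_reads += pos_reads[pos]
        if (pos - window.anchor) % phase_length == 0:
            reg_reads += pos_reads[pos]
            max_reads = max(max_reads, pos_reads[pos])
            for seq in sorted(set(pos_seqs[pos])):
                in_register.append((seq, pos))
    ratio = reg_reads / total_reads if total_reads else 0.0
    return PhasedLocus(
        transcript_id=tid,
        window=window,
        start=start,
        end=end,
        pha_sirnas=in_register,
        max_pha_reads=max_reads,
        phased_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# initiator prediction (seed-weighted complementarity penalty)
# ---------------------------------------------------------------------------


def target_penalty_score(
    mirna: str,
    site: str,
    scoring_len: int = DEFAULT_SCORING_LENGTH,
) -> Optional[float]:
    """Complementarity penalty (expectation) of a miRNA against a site.

    The site is the target transcript subsequence 5'->3'; the miRNA pairs
    antiparallel, its position p (1-based from the 5' end) against site
    position len(site)-p.  Scored over the first ``scoring_len`` miRNA
    positions: mismatch 1.0, G:U wobble 0.5, doubled at positions 2-13.
    Returns None when the site is too short to score.
    """
    mirna = mirna.upper().replace("U", "T")
    site = site.upper().replace("U", "T")
    if len(site) < scoring_len or len(mirna) < scoring_len:
        return None
    expectation = 0.0
    for i in range(scoring_len):
        mb = mirna[i]
        tb = site[len(site) - 1 - i]
        if (mb, tb) in _WC:
            penalty = 0.0
        elif (mb, tb) in _WOBBLE:
            penalty = WOBBLE_PENALTY
        else:
            penalty = MISMATCH_PENALTY
        if _SEED_START <= i + 1 <= _SEED_END:
            penalty *= 2.0
        expectation += penalty
    return expectation


def predict_initiators(
    mirnas: Mapping[str, str],
    phased_loci: Sequence[PhasedLocus],
    transcripts: Mapping[str, str],
    max_expectation: float = DEFAULT_MAX_EXPECTATION,
    flank: int = DEFAULT_FLANK,
    max_shift: int = DEFAULT_MAX_SHIFT,
    scoring_len: int = DEFAULT_SCORING_LENGTH,
    phase_length: int = PHASE_LENGTH,
) -> List[InitiatorCall]:
    """Predict the miRNA trigger of each phased locus.

    A call requires a target site with expectation <= max_expectation lying
    within ``flank`` nt of the phased region, whose predicted cleavage
    position (opposite miRNA positions 10-11, i.e. the 5' end of the
    downstream fragment) sits within ``max_shift`` nt of the locus phase
    register.  The best call per locus (lowest expectation, then smallest
    shift) is attached to the locus and returned.
    """
    calls: List[InitiatorCall] = []
    for locus in phased_loci:
        tseq = transcripts[locus.transcript_id]
        search_lo = max(0, locus.start - flank)
        search_hi = min(len(tseq), locus.end + flank)
        best: Optional[InitiatorCall] = None
        for mid in sorted(mirnas):
            mseq = mirnas[mid]
            mlen = len(mseq)
            for t1 in range(search_lo + mlen, search_hi + 1):
                t0 = t1 - mlen
                site = tseq[t0:t1]
                e = target_penalty_score(mseq, site, scoring_len)
                if e is None or e > max_expectation:
                    continue
                # distance from site span to phased region must be <= flank
                dist = max(locus.start - t1, t0 - locus.end, 0)
                if dist > flank:
                    continue
                cleavage = t1 - 10
                off = (cleavage - locus.window.anchor) % phase_length
                shift = min(off, phase_length - off)
                if shift > max_shift:
                    continue
                call = InitiatorCall(
                    mirna_id=mid,
                    locus_id=locus.locus_id,
                    site_start=t0,
                    site_end=t1,
                    expectation=e,
                    cleavage_position=cleavage,
                    register_shift=shift,
                )
                if best is None or (call.expectation, call.register_shift) < (
                    best.expectation,
                    best.register_shift,
                ):
                    best = call
        if best is not None:
            locus.trigger = best
            calls.append(best)
    return calls


def locus_diagram(locus: PhasedLocus, transcripts: Mapping[str, str], width: int = 80) -> str:
    """Plain-text per-locus diagram: register ticks and siRNA positions."""
    lines = [
        f"locus {locus.locus_id}  p={locus.window.p_value:.3e}  "
        f"ratio={locus.phased_ratio:.2f}  span=[{locus.start},{locus.end})"
    ]
    span = locus.end - locus.start
    scale = max(1, -(-span // width))
    track = ["-"] * (span // scale + 1)
    for pos in range(locus.start, locus.end, locus.window.phase_length):
        if (pos - locus.window.anchor) % locus.window.phase_length == 0:
            track[(pos - locus.start) // scale] = "|"
    lines.append("".join(track))
    reads = ["."] * (span // scale + 1)
    for _, pos in locus.pha_sirnas:
        reads[(pos - locus.start) // scale] = "*"
    lines.append("".join(reads))
    if locus.trigger:
        t = locus.trigger
        lines.append(
            f"trigger {t.mirna_id} site=[{t.site_start},{t.site_end}) "
            f"e={t.expectation:.1f} cleavage={t.cleavage_position} shift={t.register_shift}"
        )
    return "\n".join(lines)
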