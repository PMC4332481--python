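"""Synthetic genome, annotations and sRNA libraries with known ground truth.

Every signal class the pipeline detects is implanted into an i.i.d. random
background: miRNA hairpins (true reverse-complement stems with 2-nt 3'
overhangs), repeat features of several classes (a subset duplicated across
the two sub-genome references), 21-nt phased transcripts with an implanted
miRNA trigger site, cis-NAT transcript pairs in all four orientations,
trans-NAT pairs sharing a >= 100 nt complementary block, plus positional
background noise.  A TruthManifest records everything needed to score
pipeline calls as TP/FP/FN.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .sequence_io import (
    GenomicInterval,
    RepeatFeature,
    TranscriptModel,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

PHASE_LENGTH = 21


@dataclass
class SimulationConfig:
    seed: int = 42
    genome_length: int = 200_000  # split across two sub-genome references
    n_hairpins: int = 20
    n_conserved: int = 8
    n_repeats: int = 50
    n_shared_repeats: int = 10
    repeat_length: int = 400
    n_phased: int = 10
    n_decoy_transcripts: int = 40
    pha_cycles: int = 8
    n_cis: int = 8
    n_trans: int = 6
    n_trans_decoys: int = 3
    n_background: int = 300
    mature_reads: int = 100
    mature_star_ratio: int = 20
    strand_noise_reads: int = 2
    pad: int = 250

    def validate(self) -> None:
        for name in (
            "genome_length", "n_hairpins", "n_repeats", "n_phased", "n_cis",
            "n_trans", "n_background", "mature_reads", "mature_star_ratio",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_conserved > self.n_hairpins:
            raise ValueError("n_conserved > n_hairpins")


@dataclass
class TruthManifest:
    seed: int
    config: dict
    hairpins: List[dict] = field(default_factory=list)
    repeats: List[dict] = field(default_factory=list)
    rasirna_reads: Dict[str, dict] = field(default_factory=dict)
    phased: List[dict] = field(default_factory=list)
    decoy_transcripts: List[str] = field(default_factory=list)
    cis_pairs: List[dict] = field(default_factory=list)
    trans_pairs: List[dict] = field(default_factory=list)
    trans_decoys: List[dict] = field(default_factory=list)
    reads: List[dict] = field(default_factory=list)  # every simulated read

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


@dataclass
class SyntheticReference:
    genome: Dict[str, str]
    transcript_seqs: Dict[str, str]
    transcript_models: List[TranscriptModel]
    repeats: List[RepeatFeature]
    known_mirnas: Dict[str, str]
    manifest: TruthManifest


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


class _Reserver:
    """Non-overlapping placement of signal intervals with a safety pad."""

    def __init__(self, lengths: Mapping[str, int], pad: int):
        self.lengths = dict(lengths)
        self.pad = pad
        self.reserved: Dict[str, List[Tuple[int, int]]] = {r: [] for r in lengths}

    def reserve(self, rng: np.random.Generator, ref: str, length: int) -> int:
        L = self.lengths[ref]
        for _ in range(2000):
            start = int(rng.integers(self.pad, L - length - self.pad))
            if self._free(ref, start - self.pad, start + length + self.pad):
                self.reserved[ref].append((start, start + length))
                return start
        raise ValueError("signals overflow genome length; shrink counts or grow genome")

    def _free(self, ref: str, lo: int, hi: int) -> bool:
        return all(hi <= s or e <= lo for s, e in self.reserved[ref])

    def random_free_position(self, rng: np.random.Generator, ref: str, length: int) -> int:
        L = self.lengths[ref]
        for _ in range(5000):
            start = int(rng.integers(0, L - length))
            if self._free(ref, start - self.pad, start + length + self.pad):
                return start
        raise ValueError("no free background position")


def _mutate(rng: np.random.Generator, seq: str, positions: Sequence[int]) -> str:
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def _nonpairing_base(rng: np.random.Generator, partner: str) -> str:
    """A base that neither Watson-Crick nor G:U pairs with ``partner``."""
    pairs = {"A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "T": {"A", "G"}}
    choices = [b for b in "ACGT" if b not in pairs[partner]]
    return choices[int(rng.integers(0, len(choices)))]


def _build_hairpin(
    rng: np.random.Generator, mature: str, n_mismatches: int, max_tries: int = 50
) -> Tuple[str, int, int]:
    """Precursor with a mature/star duplex (2-nt 3' overhangs).

    Star core = revcomp(mature[:19]) so mature position i pairs star
    position 18-i; ``n_mismatches`` stem positions (away from the duplex
    ends) are broken deliberately.  Construction is validated: flank, loop
    and overhang draws are retried until the precursor has no accidental
    antisense self-match (which would wreck the locus strand bias) and the
    bundled folder recovers an acceptable duplex, so every implanted
    hairpin is detectable in isolation regardless of seed.
    """
    from .mirna_discovery import _overhang_consistent, validate_hairpin

    mismatches = n_mismatches
    for attempt in range(max_tries):
        if attempt == max_tries // 2:
            mismatches = 0  # pathological draws: fall back to a perfect stem
        flank5 = _random_seq(rng, 10)
        flank3 = _random_seq(rng, 10)
        loop = _random_seq(rng, 15)
        star_core = list(reverse_complement(mature[:19]))
        for j in [6, 10, 13, 8][:mismatches]:
            star_core[j] = _nonpairing_base(rng, mature[18 - j])
        star = "".join(star_core) + _random_seq(rng, 2)
        precursor = flank5 + mature + loop + star + flank3
        m_off, s_off = 10, 10 + len(mature) + len(loop)
        if reverse_complement(mature) in precursor or reverse_complement(star) in precursor:
            continue
        structure, _, accepted = validate_hairpin(
            precursor, m_off, len(mature), s_off, len(star)
        )
        if accepted and _overhang_consistent(
            structure, m_off, len(mature), s_off, len(star), shift_tolerance=3
        ):
            return precursor, m_off, s_off
    return precursor, m_off, s_off  # last resort; vanishingly unlikely


_REPEAT_CLASSES = [
    "LTR/Gypsy", "LTR/Copia", "DNA/MuDR", "DNA/En-Spm", "rRNA", "Simple_repeat",
]


def generate_reference(config: SimulationConfig) -> SyntheticReference:
    """Genome + annotations + transcripts + truth for one seeded simulation."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    half = config.genome_length // 2
    refs = ("A2", "D5")
    genome = {ref: bytearray(_random_seq(rng, half), "ascii") for ref in refs}
    reserver = _Reserver({ref: half for ref in refs}, config.pad)
    manifest = TruthManifest(seed=config.seed, config=asdict(config))

    def implant(ref: str, seq: str) -> int:
        start = reserver.reserve(rng, ref, len(seq))
        genome[ref][start : start + len(seq)] = seq.encode()
        return start

    def add_read(seq: str, count: int, origin: str) -> None:
        manifest.reads.append({"sequence": seq, "count": int(count), "origin": origin})

    # --- known miRNA catalogue -------------------------------------------
    known: Dict[str, str] = {}
    for i in range(max(config.n_conserved, 8) + 4):
        known[f"gba-miR{101 + i}a"] = _random_seq(rng, 21)

    # --- miRNA hairpins ---------------------------------------------------
    star_reads = max(1, config.mature_reads // config.mature_star_ratio)
    for i in range(config.n_hairpins):
        conserved = i < config.n_conserved
        if conserved:
            family = f"miR{101 + i}"
            base = known[f"gba-miR{101 + i}a"]
            n_subs = i % 4
            mature = _mutate(rng, base, [3, 9, 15][:n_subs])
        else:
            family = None
            mature = _random_seq(rng, 21)
        n_mm = [0, 0, 1, 2][i % 4]
        precursor, m_off, s_off = _build_hairpin(rng, mature, n_mm)
        ref = refs[i % 2]
        start = implant(ref, precursor)
        star = precursor[s_off : s_off + 21]
        manifest.hairpins.append(
            {
                "ref": ref,
                "precursor_start": start,
                "precursor_end": start + len(precursor),
                "mature": mature,
                "star": star,
                "mature_start": start + m_off,
                "star_start": start + s_off,
                "engineered_mismatches": n_mm,
                "conserved": conserved,
                "family": family,
            }
        )
        add_read(mature, config.mature_reads, f"hairpin_{i}:mature")
        add_read(star, star_reads, f"hairpin_{i}:star")
        if config.strand_noise_reads > 0:
            loop_start = start + m_off + 21 + 2
            anti = reverse_complement(
                genome[ref][loop_start : loop_start + 20].decode()
            )
            add_read(anti, config.strand_noise_reads, f"hairpin_{i}:antisense_noise")

    # --- repeats ----------------------------------------------------------
    repeats: List[RepeatFeature] = []
    n_shared = min(config.n_shared_repeats, config.n_repeats // 2)
    shared_done = 0
    i = 0
    while i < config.n_repeats:
        cls = _REPEAT_CLASSES[i % len(_REPEAT_CLASSES)]
        if shared_done < n_shared and i + 1 < config.n_repeats:
            # one identical repeat copy in each sub-genome
            seq = _random_seq(rng, config.repeat_length)
            positions = {}
            for ref in refs:
                s = implant(ref, seq)
                positions[ref] = s
                iv = GenomicInterval(ref, s, s + config.repeat_length, "+")
                repeats.append(RepeatFeature(iv, cls, ref))
                manifest.repeats.append(
                    {"ref": ref, "start": s, "end": s + config.repeat_length,
                     "class": cls, "shared": True}
                )
            src_ref = refs[0]
            base = positions[src_ref]
            for _ in range(3):
                off = int(rng.integers(0, config.repeat_length - 24))
                sub = genome[src_ref][base + off : base + off + 24].decode()
                read = sub if rng.random() < 0.5 else reverse_complement(sub)
                manifest.rasirna_reads[read] = {
                    "class": cls, "subgenomes": sorted(refs)
                }
                add_read(read, int(rng.integers(2, 9)), f"repeat_shared_{i}")
            shared_done += 1
            i += 2
            continue
        ref = refs[i % 2]
        start = reserver.reserve(rng, ref, config.repeat_length)
        iv = GenomicInterval(ref, start, start + config.repeat_length, "+")
        repeats.append(RepeatFeature(iv, cls, ref))
        manifest.repeats.append(
            {"ref": ref, "start": start, "end": start + config.repeat_length,
             "class": cls, "shared": False}
        )
        for _ in range(3):
            off = int(rng.integers(0, config.repeat_length - 24))
            sub = genome[ref][start + off : start + off + 24].decode()
            read = sub if rng.random() < 0.5 else reverse_complement(sub)
            manifest.rasirna_reads[read] = {"class": cls, "subgenomes": [ref]}
            add_read(read, int(rng.integers(2, 9)), f"repeat_{i}")
        i += 1

    # --- phased transcripts (with an implanted miRNA trigger) ------------
    transcript_seqs: Dict[str, str] = {}
    anchor = 100
    for i in range(config.n_phased):
        tid = f"PHAS{i + 1:03d}"
        length = anchor + config.pha_cycles * PHASE_LENGTH + 100
        seq = list(_random_seq(rng, length))
        trigger_idx = i % max(1, config.n_hairpins)
        trigger = manifest.hairpins[trigger_idx]["mature"] if manifest.hairpins else None
        if trigger:
            site = reverse_complement(trigger)
            seq[anchor - 11 : anchor + 10] = site
        transcript_seqs[tid] = "".join(seq)
        positions = [anchor + PHASE_LENGTH * t for t in range(config.pha_cycles)]
        read_seqs = []
        for pos in positions:
            read = transcript_seqs[tid][pos : pos + PHASE_LENGTH]
            read_seqs.append(read)
            add_read(read, int(rng.integers(5, 13)), f"phased_{tid}")
        manifest.phased.append(
            {
                "transcript_id": tid,
                "anchor": anchor,
                "cycles": config.pha_cycles,
                "trigger_mirna": trigger,
                "trigger_hairpin": trigger_idx if trigger else None,
                "site_start": anchor - 11,
                "site_end": anchor + 10,
                "reads": read_seqs,
            }
        )

    # --- unphased decoy transcripts --------------------------------------
    for i in range(config.n_decoy_transcripts):
        tid = f"DECOY{i + 1:03d}"
        seq = _random_seq(rng, 300)
        transcript_seqs[tid] = seq
        # positions pairwise non-congruent mod 21: at most one occupied
        # register slot in any window, so phasing can never look enriched
        residues = rng.permutation(PHASE_LENGTH)[:6]
        positions = sorted(
            int(r) + PHASE_LENGTH * int(rng.integers(0, (300 - 26) // PHASE_LENGTH))
            for r in residues
        )
        for pos in positions:
            add_read(seq[pos : pos + PHASE_LENGTH], int(rng.integers(5, 10)), f"decoy_{tid}")
        manifest.decoy_transcripts.append(tid)

    # --- cis-NAT pairs ----------------------------------------------------
    transcript_models: List[TranscriptModel] = []
    geometries = {
        "convergent": (("+", 0, 500), ("-", 380, 880)),
        "divergent": (("-", 0, 500), ("+", 380, 880)),
        "enclosed": (("+", 0, 800), ("-", 200, 500)),
        "coincided": (("+", 0, 500), ("-", 0, 500)),
    }
    orientation_cycle = list(geometries)
    for i in range(config.n_cis):
        orientation = orientation_cycle[i % 4]
        (strand_a, a0, a1), (strand_b, b0, b1) = geometries[orientation]
        region_len = max(a1, b1)
        ref = refs[i % 2]
        base = reserver.reserve(rng, ref, region_len)
        ids = (f"CISA{i + 1:03d}", f"CISB{i + 1:03d}")
        spans = ((a0, a1, strand_a), (b0, b1, strand_b))
        for tid, (s, e, strand) in zip(ids, spans):
            gs, ge = base + s, base + e
            mid = (e - s - 100) // 2
            exons = ((gs, gs + mid), (gs + mid + 100, ge))
            model = TranscriptModel(tid, tid, GenomicInterval(ref, gs, ge, strand), exons)
            transcript_models.append(model)
            sub = genome[ref][gs:ge].decode()
            transcript_seqs[tid] = sub if strand == "+" else reverse_complement(sub)
        ov_lo, ov_hi = base + max(a0, b0), base + min(a1, b1)
        for j in range(5):
            length = int(rng.integers(21, 25))
            pos = int(rng.integers(ov_lo, ov_hi - length))
            sub = genome[ref][pos : pos + length].decode()
            read = sub if j < 3 else reverse_complement(sub)
            add_read(read, int(rng.integers(2, 5)), f"cis_{i}:overlap")
        manifest.cis_pairs.append(
            {
                "pair_id": "|".join(sorted(ids)),
                "transcript_a": ids[0],
                "transcript_b": ids[1],
                "ref": ref,
                "orientation": orientation,
                "overlap": [ov_lo, ov_hi],
            }
        )

    # --- trans-NAT pairs --------------------------------------------------
    for i in range(config.n_trans):
        ida, idb = f"TRA{i + 1:03d}", f"TRB{i + 1:03d}"
        seq_a = _random_seq(rng, 500)
        block = seq_a[175:325]
        embedded = list(reverse_complement(block))
        mut_positions = list(range(10, 150, 20))
        embedded = _mutate(rng, "".join(embedded), mut_positions)
        seq_b = _random_seq(rng, 175) + embedded + _random_seq(rng, 175)
        transcript_seqs[ida] = seq_a
        transcript_seqs[idb] = seq_b
        for tid, lo, hi in ((ida, 175, 325), (idb, 175, 325)):
            for _ in range(4):
                pos = int(rng.integers(lo, hi - 21))
                add_read(transcript_seqs[tid][pos : pos + 21], int(rng.integers(2, 5)), f"trans_{i}")
        manifest.trans_pairs.append(
            {"pair_id": "|".join(sorted((ida, idb))), "transcript_a": ida,
             "transcript_b": idb, "block_length": 150}
        )

    for i in range(config.n_trans_decoys):
        ida, idb = f"TDA{i + 1:03d}", f"TDB{i + 1:03d}"
        seq_a = _random_seq(rng, 500)
        block = seq_a[175:325]
        # same polarity (complemented but not reversed): must NOT pass
        complemented = block.translate(str.maketrans("ACGT", "TGCA"))
        seq_b = _random_seq(rng, 175) + complemented + _random_seq(rng, 175)
        transcript_seqs[ida] = seq_a
        transcript_seqs[idb] = seq_b
        manifest.trans_decoys.append(
            {"pair_id": "|".join(sorted((ida, idb))), "transcript_a": ida,
             "transcript_b": idb}
        )

    # --- background noise -------------------------------------------------
    for i in range(config.n_background):
        ref = refs[i % 2]
        length = int(rng.integers(18, 27))
        start = reserver.random_free_position(rng, ref, length)
        sub = genome[ref][start : start + length].decode()
        read = sub if rng.random() < 0.5 else reverse_complement(sub)
        add_read(read, int(rng.integers(1, 4)), "background")

    return SyntheticReference(
        genome={ref: bytes(genome[ref]).decode() for ref in refs},
        transcript_seqs=transcript_seqs,
        transcript_models=transcript_models,
        repeats=repeats,
        known_mirnas=known,
        manifest=manifest,
    )


def simulate_reads(
    reference: SyntheticReference,
    config: SimulationConfig,
    library_ids: Tuple[str, str] = ("L1", "L2"),
) -> Dict[str, Dict[str, int]]:
    """Collapsed (sequence -> count) libraries from the manifest read plan.

    Each read's total count is split between the two libraries binomially
    (seeded), emulating two independently sampled datasets.
    """
    rng = np.random.default_rng(config.seed + 1)
    libraries: Dict[str, Dict[str, int]] = {lib: {} for lib in library_ids}
    totals: Dict[str, int] = {}
    for entry in reference.manifest.reads:
        seq = entry["sequence"]
        totals[seq] = totals.get(seq, 0) + entry["count"]
    for seq in sorted(totals):
        total = totals[seq]
        in_first = int(rng.binomial(total, 0.5))
        split = {library_ids[0]: in_first, library_ids[1]: total - in_first}
        for lib, n in split.items():
            if n > 0:
                libraries[lib][seq] = libraries[lib].get(seq, 0) + n
    return libraries


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def _reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if ov == 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _prf(tp: int, fp: int, fn: int) -> dict:
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}


def evaluate_recovery(results: Mapping, manifest: TruthManifest) -> Dict[str, dict]:
    """Score pipeline calls against the manifest, per signal class.

    ``results`` is the structured output of the classify stage (see
    cli.run_pipeline): keys mirna_loci, pyts, initiators, cis_pairs,
    trans_pairs, rasirna, mirna_matures.
    """
    report: Dict[str, dict] = {}

    # miRNA loci: >= 50% reciprocal overlap on the same reference
    true_loci = [
        (h["ref"], (h["precursor_start"], h["precursor_end"])) for h in manifest.hairpins
    ]
    called = [
        (l.precursor.ref, (l.precursor.start, l.precursor.end))
        for l in results.get("mirna_loci", [])
    ]
    matched_truth: Set[int] = set()
    tp = 0
    for ref, span in called:
        hit = None
        for idx, (tref, tspan) in enumerate(true_loci):
            if idx in matched_truth or tref != ref:
                continue
            if _reciprocal_overlap(span, tspan) >= 0.5:
                hit = idx
                break
        if hit is None:
            tp_flag = False
        else:
            matched_truth.add(hit)
            tp_flag = True
        tp += tp_flag
    report["mirna_loci"] = _prf(tp, len(called) - tp, len(true_loci) - tp)

    # conservation calls on recovered matures
    truth_by_mature = {h["mature"]: h for h in manifest.hairpins}
    assignments = results.get("family_assignments", {})
    matures = results.get("mirna_matures", {})
    checked = correct = 0
    for mid, assignment in assignments.items():
        truth = truth_by_mature.get(matures.get(mid, ""))
        if truth is None:
            continue
        checked += 1
        want = "conserved" if truth["conserved"] else "lineage_specific"
        ok = assignment.conservation == want
        if ok and truth["conserved"]:
            ok = assignment.family == truth["family"]
        correct += ok
    report["conservation"] = {
        "checked": checked,
        "correct": correct,
        "accuracy": correct / checked if checked else None,
    }

    # ra-siRNAs: distinct sequences, class via the coarse group
    from .rasirna import class_group

    truth_reads = manifest.rasirna_reads
    called_ra = {a.sequence: a for a in results.get("rasirna", [])}
    tp = sum(1 for seq in called_ra if seq in truth_reads)
    fp = len(called_ra) - tp
    fn = len(truth_reads) - tp
    class_ok = sum(
        1
        for seq, a in called_ra.items()
        if seq in truth_reads
        and class_group(a.primary_class) == class_group(truth_reads[seq]["class"])
    )
    report["rasirna"] = {
        **_prf(tp, fp, fn),
        "class_accuracy": class_ok / tp if tp else None,
    }

    # PYTs: transcript id + anchor in the implanted register
    true_pyts = {p["transcript_id"]: p for p in manifest.phased}
    called_pyts = results.get("pyts", [])
    tp = fp = 0
    seen: Set[str] = set()
    sig_truth = 0
    triggers_called = 0
    for locus in called_pyts:
        truth = true_pyts.get(locus.transcript_id)
        in_register = (
            truth is not None
            and (locus.window.anchor - truth["anchor"]) % PHASE_LENGTH == 0
        )
        if in_register and locus.transcript_id not in seen:
            seen.add(locus.transcript_id)
            tp += 1
            if locus.window.p_value < 1e-3:
                sig_truth += 1
            if (
                locus.trigger is not None
                and matures.get(locus.trigger.mirna_id, "") == truth["trigger_mirna"]
            ):
                triggers_called += 1
        else:
            fp += 1
    decoy_calls = sum(
        1 for l in called_pyts if l.transcript_id in set(manifest.decoy_transcripts)
    )
    report["pyts"] = {
        **_prf(tp, fp, len(true_pyts) - tp),
        "all_significant": sig_truth == tp,
        "triggers_called": triggers_called,
        "decoy_calls": decoy_calls,
        "decoy_clean_fraction": (
            1.0 - decoy_calls / len(manifest.decoy_transcripts)
            if manifest.decoy_transcripts
            else None
        ),
    }

    # cis pairs: exact pair id; orientation accuracy on matches
    true_cis = {p["pair_id"]: p["orientation"] for p in manifest.cis_pairs}
    called_cis = {p.pair_id: p.orientation for p in results.get("cis_pairs", [])}
    tp = sum(1 for pid in called_cis if pid in true_cis)
    orient_ok = sum(
        1 for pid, o in called_cis.items() if true_cis.get(pid) == o
    )
    report["cis_pairs"] = {
        **_prf(tp, len(called_cis) - tp, len(true_cis) - tp),
        "orientation_accuracy": orient_ok / tp if tp else None,
    }

    # trans pairs: exact pair id; decoys must stay out
    true_trans = {p["pair_id"] for p in manifest.trans_pairs}
    decoy_trans = {p["pair_id"] for p in manifest.trans_decoys}
    called_trans = {p.pair_id for p in results.get("trans_pairs", [])}
    tp = len(called_trans & true_trans)
    report["trans_pairs"] = {
        **_prf(tp, len(called_trans - true_trans), len(true_trans - called_trans)),
        "decoys_called": len(called_trans & decoy_trans),
    }

    return report


# ---------------------------------------------------------------------------
# serialization of the dataset in pipeline-consumable formats
# ---------------------------------------------------------------------------


def write_dataset(reference: SyntheticReference, config: SimulationConfig, outdir) -> Dict[str, str]:
    """Write FASTA/GFF3/TSV/JSON files the classify stage consumes."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _path(name: str) -> str:
        p = os.path.join(str(outdir), name)
        paths[name] = p
        return p

    with open(_path("genome.fasta"), "w") as fh:
        for ref in sorted(reference.genome):
            fh.write(f">{ref}\n{reference.genome[ref]}\n")
    with open(_path("transcripts.fasta"), "w") as fh:
        for tid in sorted(reference.transcript_seqs):
            fh.write(f">{tid}\n{reference.transcript_seqs[tid]}\n")
    with open(_path("transcripts.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for t in reference.transcript_models:
            iv = t.interval
            fh.write(
                f"{iv.ref}\tsrnakit\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={t.id}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{iv.ref}\tsrnakit\texon\t{s + 1}\t{e}\t.\t{iv.strand}\t.\tParent={t.id}\n"
                )
    with open(_path("repeats.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for r in reference.repeats:
            iv = r.interval
            fh.write(
                f"{iv.ref}\tsrnakit\trepeat_region\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"repeat_class={r.repeat_class};subgenome={r.subgenome}\n"
            )
    with open(_path("known_mirnas.fasta"), "w") as fh:
        for name in sorted(reference.known_mirnas):
            fh.write(f">{name}\n{reference.known_mirnas[name]}\n")
    libraries = simulate_reads(reference, config)
    for lib, counts in libraries.items():
        with open(_path(f"reads_{lib}.tsv"), "w") as fh:
            for seq in sorted(counts):
                fh.write(f"{seq}\t{counts[seq]}\n")
    with open(_path("manifest.json"), "w") as fh:
        fh.write(reference.manifest.to_json())
    return paths
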