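"""Repeat-associated siRNA assignment and taxonomy summary."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .sequence_io import AlignmentHit, RepeatFeature

logger = logging.getLogger(__name__)

# Controlled vocabulary of repeat classes and the coarse group each belongs
# to.  Multi-class sRNAs are totalled once under the highest-priority group:
# retrotransposon > DNA transposon > rRNA > simple repeat > others.
GROUP_RETRO = "Retrotransposon"
GROUP_DNA = "Transposon"
GROUP_RRNA = "rRNA"
GROUP_SIMPLE = "Simple repeat"
GROUP_OTHERS = "Others"

GROUP_PRIORITY = [GROUP_RETRO, GROUP_DNA, GROUP_RRNA, GROUP_SIMPLE, GROUP_OTHERS]

CLASS_VOCABULARY: Dict[str, str] = {
    "DNA/MuDR": GROUP_DNA,
    "DNA/En-Spm": GROUP_DNA,
    "DNA": GROUP_DNA,
    "DNA/hAT": GROUP_DNA,
    "DNA/Harbinger": GROUP_DNA,
    "DNA/TcMar": GROUP_DNA,
    "DNA/Mite": GROUP_DNA,
    "RC/Helitron": GROUP_DNA,
    "LTR": GROUP_RETRO,
    "LTR/Gypsy": GROUP_RETRO,
    "LTR/Copia": GROUP_RETRO,
    "Non LTR": GROUP_RETRO,
    "Retroelement": GROUP_RETRO,
    "LINE": GROUP_RETRO,
    "SINE": GROUP_RETRO,
    "rRNA": GROUP_RRNA,
    "Simple_repeat": GROUP_SIMPLE,
    "Simple repeat": GROUP_SIMPLE,
    "Others": GROUP_OTHERS,
}


def normalize_repeat_class(label: str) -> str:
    if label in CLASS_VOCABULARY:
        return label
    prefix = label.split("/", 1)[0]
    if prefix in ("LTR", "DNA"):
        return prefix
    logger.warning("unknown repeat class %r mapped to Others", label)
    return "Others"


def class_group(label: str) -> str:
    return CLASS_VOCABULARY[normalize_repeat_class(label)]


@dataclass
class RasirnaAssignment:
    """One sRNA attributed to repeat features, with full class detail."""

    sequence: str
    primary_class: str
    all_classes: Tuple[str, ...]
    subgenomes: FrozenSet[str]
    hits: List[AlignmentHit] = field(default_factory=list)


def assign_rasirnas(
    hits: Sequence[AlignmentHit],
    repeats: Sequence[RepeatFeature],
    exclude: Set[str] = frozenset(),
) -> List[RasirnaAssignment]:
    """Attribute sRNA hits to repeat features (>= 1 nt overlap).

    sRNAs in ``exclude`` (e.g. identified miRNA sequences) are skipped.  The
    primary class of a multi-class sRNA follows the group priority order,
    tie-broken by class label; every overlapped class is kept in the detail.
    """
    by_ref: Dict[str, List[RepeatFeature]] = {}
    for feat in repeats:
        by_ref.setdefault(feat.interval.ref, []).append(feat)
    for feats in by_ref.values():
        feats.sort(key=lambda f: f.interval.start)

    per_srna: Dict[str, Dict] = {}
    for hit in hits:
        if hit.sequence in exclude:
            continue
        for feat in by_ref.get(hit.interval.ref, ()):
            if feat.interval.start >= hit.interval.end:
                break
            if hit.interval.overlap_length(feat.interval) >= 1:
                entry = per_srna.setdefault(
                    hit.sequence, {"classes": set(), "subs": set(), "hits": []}
                )
                entry["classes"].add(normalize_repeat_class(feat.repeat_class))
                if feat.subgenome:
                    entry["subs"].add(feat.subgenome)
                entry["hits"].append(hit)

    prio = {g: i for i, g in enumerate(GROUP_PRIORITY)}
    out: List[RasirnaAssignment] = []
    for seq in sorted(per_srna):
        entry = per_srna[seq]
        classes = sorted(entry["classes"])
        primary = min(classes, key=lambda c: (prio[class_group(c)], c))
        out.append(
            RasirnaAssignment(
                sequence=seq,
                primary_class=primary,
                all_classes=tuple(classes),
                subgenomes=frozenset(entry["subs"]),
                hits=entry["hits"],
            )
        )
    return out


def summarize_rasirna(
    assignments: Sequence[RasirnaAssignment],
    subgenome_a: str = "A2",
    subgenome_b: str = "D5",
) -> pd.DataFrame:
    """Distinct-sRNA taxonomy table: class x {A2-only, D5-only, both, total}.

    Each sRNA counts once, under its primary class; total = A2 + D5 + both
    per class by construction.
    """
    rows: Dict[str, Dict[str, int]] = {}
    for a in assignments:
        row = rows.setdefault(
            a.primary_class, {subgenome_a: 0, subgenome_b: 0, "both": 0, "total": 0}
        )
        in_a = subgenome_a in a.subgenomes
        in_b = subgenome_b in a.subgenomes
        if in_a and in_b:
            row["both"] += 1
        elif in_a:
            row[subgenome_a] += 1
        elif in_b:
            row[subgenome_b] += 1
        else:
            continue
        row["total"] += 1
    order = sorted(
        rows,
        key=lambda c: ({g: i for i, g in enumerate(GROUP_PRIORITY)}[class_group(c)], c),
    )
    df = pd.DataFrame(
        [{"repeat_class": c, **rows[c]} for c in order],
        columns=["repeat_class", subgenome_a, subgenome_b, "both", "total"],
    )
    if df.empty:
        df = pd.DataFrame(
            columns=["repeat_class", subgenome_a, subgenome_b, "both", "total"]
        )
    return df
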