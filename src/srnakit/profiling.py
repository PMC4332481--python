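"""Length and 5'-nucleotide composition profiles per sRNA class."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import pandas as pd

from .nat import NatPair
from .sequence_io import SmallRNA

MIN_LEN, MAX_LEN = 18, 26
_NUCS = ("A", "C", "G", "U")


def length_distribution(
    srnas: Sequence[SmallRNA],
    weighted: bool = False,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> Dict[int, int]:
    """Counts per length; the weighted variant sums read counts instead."""
    hist = {length: 0 for length in range(min_len, max_len + 1)}
    for s in srnas:
        if s.length in hist:
            hist[s.length] += s.total_count if weighted else 1
    return hist


def five_prime_composition(
    srnas: Sequence[SmallRNA], weighted: bool = False
) -> Dict[str, float]:
    """Fraction of class members (or reads) starting with each nucleotide."""
    if not srnas:
        return {}
    tally = {n: 0 for n in _NUCS}
    for s in srnas:
        first = "U" if s.sequence[0] == "T" else s.sequence[0]
        if first in tally:
            tally[first] += s.total_count if weighted else 1
    total = sum(tally.values())
    if total == 0:
        return {}
    return {n: tally[n] / total for n in _NUCS}


def overlap_length_histogram(
    pairs: Sequence[NatPair], bin_width: int = 100, max_bin: int = 1000
) -> Dict[str, int]:
    """Binned overlap lengths; the last bin collects everything > max_bin."""
    edges = list(range(0, max_bin, bin_width))
    hist = {f"[{lo},{lo + bin_width})": 0 for lo in edges}
    hist[f">{max_bin}"] = 0
    for p in pairs:
        if p.overlap_length > max_bin:
            hist[f">{max_bin}"] += 1
        else:
            lo = (p.overlap_length // bin_width) * bin_width
            if lo == max_bin:
                lo -= bin_width
            hist[f"[{lo},{lo + bin_width})"] += 1
    return hist


def class_profile_table(
    classes: Dict[str, Sequence[SmallRNA]], weighted: bool = False
) -> pd.DataFrame:
    """Tidy (class, metric, key, value) table for all classes."""
    rows: List[dict] = []
    for label in sorted(classes):
        members = classes[label]
        for length, value in length_distribution(members, weighted).items():
            rows.append(
                {"class": label, "metric": "length", "key": str(length), "value": value}
            )
        for nuc, frac in five_prime_composition(members, weighted).items():
            rows.append(
                {"class": label, "metric": "five_prime", "key": nuc, "value": frac}
            )
    return pd.DataFrame(rows, columns=["class", "metric", "key", "value"])


def plot_profiles(table: pd.DataFrame, out_path) -> Optional[str]:
    """Optional bar-chart rendering; silently skipped without matplotlib."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover
        return None
    classes = sorted(table["class"].unique())
    fig, axes = plt.subplots(len(classes), 2, figsize=(10, 3 * max(1, len(classes))), squeeze=False)
    for i, label in enumerate(classes):
        sub = table[table["class"] == label]
        for j, metric in enumerate(("length", "five_prime")):
            data = sub[sub["metric"] == metric]
            axes[i][j].bar(data["key"], data["value"])
            axes[i][j].set_title(f"{label}: {metric}")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return str(out_path)
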