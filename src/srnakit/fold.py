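"""RNA secondary structure: a pluggable folding contract.

A fold function maps a sequence (DNA or RNA alphabet) to one dot-bracket
string of equal length.  The bundled default is a stacking-aware variant of
Nussinov base-pair maximization (pair weights GC=3 > AU=2 > GU=1, a bonus
for every stacked pair, minimum hairpin loop 3), so no external folding
library is ever required.  If ViennaRNA's python bindings are importable,
:func:`best_available_fold` prefers its MFE structure.
"""

from __future__ import annotations

from typing import Callable, List, Optional

import numpy as np

FoldFunction = Callable[[str], str]

_PAIR_SCORES = {
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "C"): 3, ("C", "G"): 3,
    ("G", "T"): 1, ("T", "G"): 1,
}

MIN_LOOP = 3
STACK_BONUS = 2
_NEG = -(10**9)


def _pair_score_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    scores = np.zeros((n, n), dtype=np.int64)
    for (a, b), w in _PAIR_SCORES.items():
        scores[(arr[:, None] == ord(a)) & (arr[None, :] == ord(b))] = w
    return scores


def nussinov_fold(seq: str, min_loop: int = MIN_LOOP) -> str:
    """Stacking-aware weighted base-pair maximization (WC + G:U pairs).

    Two-matrix dynamic program over closed intervals: V[i,j] is the best
    score given i pairs j (with a bonus when (i+1, j-1) stacks directly
    underneath), W[i,j] the best score overall.  O(n^3) with the
    bifurcation maximum vectorized; fine to ~600 nt, which covers any
    precursor this package extracts.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    if n == 0:
        return ""
    pair_score = _pair_score_matrix(seq)
    can = pair_score > 0
    V = np.full((n, n), _NEG, dtype=np.int64)
    W = np.zeros((n, n), dtype=np.int64)

    for span in range(min_loop + 2, n + 1):
        for i in range(n - span + 1):
            j = i + span - 1
            if can[i, j]:
                inner = W[i + 1, j - 1] if span > 2 else 0
                v = pair_score[i, j] + inner
                if span >= min_loop + 4 and can[i + 1, j - 1]:
                    stacked = pair_score[i, j] + V[i + 1, j - 1] + STACK_BONUS
                    if stacked > v:
                        v = stacked
                V[i, j] = v
            best = W[i, j - 1]
            ks = np.nonzero(can[i : j - min_loop, j])[0]
            if ks.size:
                ks = ks + i
                left = np.where(ks > i, W[i, np.maximum(ks - 1, 0)], 0)
                vals = left + V[ks, j]
                k_best = int(vals.max())
                if k_best > best:
                    best = k_best
            W[i, j] = best

    structure = ["."] * n
    stack: List[tuple] = [("W", 0, n - 1)]
    while stack:
        kind, i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        if kind == "W":
            if W[i, j] == W[i, j - 1]:
                stack.append(("W", i, j - 1))
                continue
            for k in range(i, j - min_loop):
                if not can[k, j]:
                    continue
                left = W[i, k - 1] if k > i else 0
                if left + V[k, j] == W[i, j]:
                    stack.append(("V", k, j))
                    if k > i:
                        stack.append(("W", i, k - 1))
                    break
        else:  # V: i pairs j
            structure[i] = "("
            structure[j] = ")"
            if (
                j - i + 1 >= min_loop + 4
                and can[i + 1, j - 1]
                and V[i, j] == pair_score[i, j] + V[i + 1, j - 1] + STACK_BONUS
            ):
                stack.append(("V", i + 1, j - 1))
            elif j - 1 >= i + 1:
                stack.append(("W", i + 1, j - 1))
    return "".join(structure)


def _vienna_fold(seq: str) -> str:  # pragma: no cover - optional dependency
    import RNA

    structure, _ = RNA.fold(seq.upper().replace("T", "U"))
    return structure


def best_available_fold() -> FoldFunction:
    """MFE folding when ViennaRNA bindings exist, else the bundled fallback."""
    try:  # pragma: no cover - environment dependent
        import RNA  # noqa: F401

        return _vienna_fold
    except ImportError:
        return nussinov_fold


def pairing_partners(structure: str) -> List[Optional[int]]:
    """Partner index per position from a dot-bracket string (None = unpaired)."""
    partners: List[Optional[int]] = [None] * len(structure)
    stack: List[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            partners[i] = j
            partners[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return partners
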