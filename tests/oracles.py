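"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — exhaustive enumeration, O(n^2)
pairwise comparison, dict-based counting — and shares no code with the
package's optimized paths.
"""

from __future__ import annotations

import math
import re
from itertools import combinations

PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}
MIN_LOOP = 3


def enumerate_structures(residues: str):
    """Yield every nested canonical pair set (as a sorted tuple, 1-based)."""
    n = len(residues)

    memo = {}

    def rec(i: int, j: int):
        # all structures on 0-based inclusive [i, j]
        if (i, j) in memo:
            return memo[(i, j)]
        if i >= j:
            out = [()]
        else:
            out = []
            for left in rec(i + 1, j):
                out.append(left)
            for k in range(i + MIN_LOOP + 1, j + 1):
                if (residues[i], residues[k]) not in PAIR_WEIGHT:
                    continue
                for inner in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(tuple(sorted(((i + 1, k + 1),) + inner + right)))
        memo[(i, j)] = out
        return out

    if n == 0:
        yield ()
        return
    yield from rec(0, n - 1)


def structure_score(residues: str, pairs) -> int:
    return sum(PAIR_WEIGHT[(residues[i - 1], residues[j - 1])] for i, j in pairs)


def exhaustive_fold(residues: str):
    """Best (score, lexicographically-smallest sorted pair tuple)."""
    best_score = -1
    best_pairs = None
    for pairs in enumerate_structures(residues):
        s = structure_score(residues, pairs)
        key = tuple(sorted(pairs))
        if s > best_score or (s == best_score and key < best_pairs):
            best_score = s
            best_pairs = key
    return best_score, best_pairs


def pairwise_auc(scores, labels) -> float:
    """Mann-Whitney AUC by explicit pair comparison, ties counted half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def longhand_metrics(tp: int, fp: int, tn: int, fn: int):
    ac = (tp + tn) / (tp + fp + tn + fn)
    se = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    d = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / math.sqrt(d) if d else 0.0
    return ac, se, sp, mcc


def runs_of_dots(db: str):
    """(start, end, length) of each maximal '.' run, 1-based, via regex."""
    return [(m.start() + 1, m.end(), m.end() - m.start())
            for m in re.finditer(r"\.+", db)]


def stem_runs_naive(pairs):
    """Stacked-run lengths found by scanning every pair as a run start."""
    pairs = set(pairs)
    lengths = []
    for i, j in pairs:
        if (i - 1, j + 1) in pairs:
            continue  # not a run start
        length = 0
        while (i, j) in pairs:
            length += 1
            i, j = i + 1, j - 1
        lengths.append(length)
    return lengths


def count_word_pairs(residues: str, k: int, n_bins: int, relative: bool):
    """Dict-based (word_i, word_j, bin) counts over all start pairs i < j."""
    L = len(residues)
    words = [residues[i : i + k] for i in range(L - k + 1)]
    counts: dict = {}
    for a, b in combinations(range(len(words)), 2):
        if relative:
            bin_ = min(n_bins * (b - a) // L, n_bins - 1)
        else:
            bin_ = 0
        key = (words[a], words[b], bin_)
        counts[key] = counts.get(key, 0) + 1
    return counts


def boltzmann_table(pos_counts: dict, neg_counts: dict, eps: float):
    """-ln frequency-ratio table from two raw count dicts."""
    tp = sum(pos_counts.values())
    tn = sum(neg_counts.values())
    keys = set(pos_counts) | set(neg_counts)
    out = {}
    for key in keys:
        fp = pos_counts.get(key, 0) / tp if tp else 0.0
        fn = neg_counts.get(key, 0) / tn if tn else 0.0
        out[key] = -math.log((fp + eps) / (fn + eps))
    return out
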