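"""Seeded synthetic sequences: stem-loop hairpins and codon-structured CDS.

The generators emulate the two sequence classes the classifier is trained
on — miRBase-style pre-miRNA stem-loops (a random 5' arm, a loop, and the
arm's reverse complement carrying point mutations) and protein-coding
sequence (AUG start, codon usage drawn from a fixed stylized table with no
in-frame stop until the terminal one).  They are pure functions of their
parameters and seed, so every test and benchmark in the package is
reproducible without any download.

``make_benchmark`` builds a labelled two-class set whose separability
decreases monotonically with a single ``difficulty`` knob in [0, 1]: the
positive arm mutation rate grows linearly with difficulty (degrading the
hairpin signal first), and each positive is replaced with probability
``difficulty**2`` by a draw from the same CDS-window sampler the negatives
use (class overlap, negligible at low difficulty).  At difficulty 1 the two
classes are identically distributed — a genuine null.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .io_seq import Sequence, write_fasta

_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: stylized relative codon usage for a dicot-like coding style; stops excluded
_CODON_WEIGHTS = {}
for _c1 in _BASES:
    for _c2 in _BASES:
        for _c3 in _BASES:
            _codon = _c1 + _c2 + _c3
            if _codon in ("UAA", "UAG", "UGA"):
                continue
            # mild 3rd-position A/U preference, as in many plant genomes
            _CODON_WEIGHTS[_codon] = 1.5 if _c3 in "AU" else 1.0
_STOPS = ("UAA", "UAG", "UGA")


def reverse_complement(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def make_hairpin(
    stem_len: int,
    loop_len: int = 8,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> Sequence:
    """A stem-loop: random 5' arm, loop, mutated reverse-complement 3' arm.

    Length is exactly ``2 * stem_len + loop_len``.  Each 3'-arm position
    mutates to a uniformly chosen different base with probability
    ``mutation_rate``.  Deterministic under ``seed``.
    """
    if stem_len < 3:
        raise ValueError("stem_len must be >= 3")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if not 0 <= mutation_rate < 1:
        raise ValueError("mutation_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    arm5 = "".join(rng.choice(list(_BASES), size=stem_len))
    loop = "".join(rng.choice(list(_BASES), size=loop_len))
    arm3 = list(reverse_complement(arm5))
    for i in range(len(arm3)):
        if rng.random() < mutation_rate:
            arm3[i] = rng.choice([b for b in _BASES if b != arm3[i]])
    return Sequence(id=f"hairpin_seed{seed}", residues=arm5 + loop + "".join(arm3))


def make_cds(n_codons: int, seed: int = 0) -> Sequence:
    """A codon-structured coding sequence (as RNA): AUG ... sense codons ... stop."""
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    rng = np.random.default_rng(seed)
    codons = list(_CODON_WEIGHTS)
    weights = np.array([_CODON_WEIGHTS[c] for c in codons], dtype=float)
    weights /= weights.sum()
    body = rng.choice(codons, size=n_codons - 2, p=weights)
    stop = rng.choice(_STOPS)
    return Sequence(id=f"cds_seed{seed}", residues="AUG" + "".join(body) + stop)


def _sample_hairpin_shape(rng: np.random.Generator) -> tuple[int, int]:
    """Stem/loop sizes spanning a compact pre-miRNA-like length range."""
    stem = int(rng.integers(18, 33))
    loop = int(rng.integers(4, 13))
    return stem, loop


def _cds_window(rng: np.random.Generator, pool: list[Sequence], length: int,
                idx: int) -> Sequence:
    src = pool[int(rng.integers(len(pool)))]
    start = int(rng.integers(len(src) - length + 1))
    return Sequence(id=f"neg_{idx}", residues=src.residues[start : start + length])


def make_benchmark(
    n_pos: int,
    n_neg: int,
    difficulty: float = 0.1,
    seed: int = 0,
) -> tuple[list[Sequence], list[Sequence]]:
    """A labelled benchmark: hairpin positives vs CDS-window negatives.

    ``difficulty`` in [0, 1]: the positive arm mutation rate is
    ``0.02 + 0.28 * difficulty`` and each positive is, with probability
    ``difficulty**2``, drawn from the negative (CDS-window) sampler instead.
    Both classes share one length distribution, so length is never the
    discriminating signal.
    """
    if not 0 <= difficulty <= 1:
        raise ValueError("difficulty must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pool = [make_cds(220, seed=int(rng.integers(2 ** 31)))
            for _ in range(max(4, (n_pos + n_neg) // 40))]
    mutation_rate = 0.02 + 0.28 * difficulty
    overlap = difficulty ** 2

    positives = []
    for i in range(n_pos):
        stem, loop = _sample_hairpin_shape(rng)
        if rng.random() < overlap:
            seq = _cds_window(rng, pool, 2 * stem + loop, i)
        else:
            hp = make_hairpin(stem, loop, mutation_rate,
                              seed=int(rng.integers(2 ** 31)))
            seq = hp
        positives.append(Sequence(id=f"pos_{i}", residues=seq.residues))

    negatives = []
    for i in range(n_neg):
        stem, loop = _sample_hairpin_shape(rng)
        negatives.append(_cds_window(rng, pool, 2 * stem + loop, i))
    return positives, negatives


def write_benchmark(
    positives: list[Sequence],
    negatives: list[Sequence],
    out_dir: str | Path,
) -> dict:
    """Write pos/neg FASTA plus a labels TSV; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "positives": out_dir / "positives.fasta",
        "negatives": out_dir / "negatives.fasta",
        "labels": out_dir / "labels.tsv",
    }
    write_fasta(positives, paths["positives"])
    write_fasta(negatives, paths["negatives"])
    with open(paths["labels"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "label"])
        for s in positives:
            w.writerow([s.id, 1])
        for s in negatives:
            w.writerow([s.id, 0])
    return paths
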