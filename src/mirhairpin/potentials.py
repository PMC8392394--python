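"""Knowledge-based k-mer pair pseudo-energies (Boltzmann inversion).

The discriminative core of the classifier: a pseudo-energy table assigns to
each (k-mer, k-mer, bin) triple the value

    E(x, b) = -ln( (F+(x, b) + eps) / (F-(x, b) + eps) )

where F+ and F- are the relative frequencies of the word pair x in bin b
over the positive (genuine hairpin) and negative (pseudo hairpin) training
sets, and eps is an additive smoothing constant (default 1 / lattice size).
Pairs over-represented among genuine precursors get negative (favourable)
energies; a sequence's feature is then an average table lookup over its own
word pairs.  Three binning schemes are used:

* ``position_specific`` — 2-mer pairs in structural contact (the two 2-mers
  flanking a base pair), binned by the 5' partner's relative sequence
  position into 34 bins; scored as 34 per-bin mean energies.
* ``distance_specific`` — all ordered k-mer pairs (k = 1..5), a single bin;
  scored as one mean energy per k.
* ``distance_dependent`` — all ordered k-mer pairs (k = 1..3) binned by
  relative separation (j - i)/L into 20 bins; scored as 20 pooled per-bin
  means plus a per-k mean and per-k standard deviation (26 values).

Distances and positions are relative (divided by L) so the potentials
transfer across the precursor length range.  Bins are half-open with the
last bin closed.  Word windows overlap.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import TrainingError
from .folding import SecondaryStructure
from .io_seq import Sequence

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

POSITION_BINS = 34
DISTANCE_DEPENDENT_BINS = 20
DISTANCE_SPECIFIC_KS = (1, 2, 3, 4, 5)
DISTANCE_DEPENDENT_KS = (1, 2, 3)


def encode_words(residues: str, k: int) -> np.ndarray:
    """Base-4 integer code of every overlapping k-mer (A=0, C=1, G=2, U=3)."""
    codes = np.fromiter((_BASE_INDEX[c] for c in residues), dtype=np.int64,
                        count=len(residues))
    if len(residues) < k:
        return np.empty(0, dtype=np.int64)
    words = np.zeros(len(residues) - k + 1, dtype=np.int64)
    for off in range(k):
        words = words * 4 + codes[off : off + len(words)]
    return words


@dataclass(frozen=True)
class PotentialTable:
    """A trained pseudo-energy lattice over (word, word, bin)."""

    scheme: str                 # position_specific | distance_specific | distance_dependent
    k: int
    n_bins: int
    entries: np.ndarray         # shape (4**k, 4**k, n_bins), float64
    epsilon: float
    provenance: str             # fingerprint of the training inputs

    def __post_init__(self) -> None:
        expected = (4 ** self.k, 4 ** self.k, self.n_bins)
        if self.entries.shape != expected:
            raise ValueError(f"entries shape {self.entries.shape} != {expected}")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("non-finite potential entries")


def _as_pairs(items) -> list[tuple[Sequence, SecondaryStructure | None]]:
    out = []
    for it in items:
        if isinstance(it, Sequence):
            out.append((it, None))
        else:
            seq, ss = it
            out.append((seq, ss))
    return out


def _contact_events(seq: Sequence, ss: SecondaryStructure, n_bins: int):
    """(word_a, word_b, bin) for each base pair: the 2-mer starting at i and
    the 2-mer ending at j, binned by i/L."""
    L = len(seq)
    words = encode_words(seq.residues, 2)
    ii, jj, bb = [], [], []
    for i, j in sorted(ss.pairs):
        if i + 1 > L or j - 1 < 1:
            continue
        ii.append(words[i - 1])        # 2-mer starting at i (1-based)
        jj.append(words[j - 2])        # 2-mer ending at j
        bb.append(min(n_bins * i // L, n_bins - 1))
    return (np.array(ii, dtype=np.int64), np.array(jj, dtype=np.int64),
            np.array(bb, dtype=np.int64))


def _pair_events(seq: Sequence, k: int, n_bins: int, relative_distance: bool):
    """(word_i, word_j, bin) over all ordered word-start pairs i < j."""
    L = len(seq)
    words = encode_words(seq.residues, k)
    m = len(words)
    if m < 2:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    iu, ju = np.triu_indices(m, k=1)
    if relative_distance:
        d = ju - iu  # position separation in nt
        bins = np.minimum(n_bins * d // L, n_bins - 1)
    else:
        bins = np.zeros(len(iu), dtype=np.int64)
    return words[iu], words[ju], bins


def _events(seq: Sequence, ss: SecondaryStructure | None, scheme: str,
            k: int, n_bins: int):
    if scheme == "position_specific":
        if ss is None:
            raise TrainingError(
                f"record {seq.id!r}: position-specific potential needs a structure"
            )
        return _contact_events(seq, ss, n_bins)
    if scheme == "distance_specific":
        return _pair_events(seq, k, n_bins, relative_distance=False)
    if scheme == "distance_dependent":
        return _pair_events(seq, k, n_bins, relative_distance=True)
    raise ValueError(f"unknown scheme {scheme!r}")


def _class_frequencies(items, scheme, k, n_bins) -> np.ndarray:
    counts = np.zeros((4 ** k, 4 ** k, n_bins), dtype=np.float64)
    for seq, ss in items:
        wa, wb, bb = _events(seq, ss, scheme, k, n_bins)
        if len(wa):
            np.add.at(counts, (wa, wb, bb), 1.0)
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def _fingerprint(pos, neg, scheme, k, n_bins) -> str:
    h = hashlib.sha256()
    h.update(f"{scheme}|k={k}|bins={n_bins}".encode())
    for tag, items in (("+", pos), ("-", neg)):
        for seq, _ in items:
            h.update(f"{tag}{seq.id}:{seq.residues}\n".encode())
    return h.hexdigest()[:16]


def train_potentials(
    pos, neg, scheme: str, k: int, n_bins: int,
    epsilon: float | None = None,
) -> PotentialTable:
    """Estimate a pseudo-energy table from labelled training sequences.

    ``pos`` and ``neg`` are lists of Sequence or (Sequence, SecondaryStructure)
    items; structures are required only by the position-specific scheme.
    Deterministic given its inputs.
    """
    pos = _as_pairs(pos)
    neg = _as_pairs(neg)
    if not pos or not neg:
        raise TrainingError("both a positive and a negative set are required")
    min_len = min(len(s) for s, _ in pos + neg)
    if k > min_len:
        raise TrainingError(f"k={k} exceeds shortest training sequence ({min_len})")
    if epsilon is None:
        epsilon = 1.0 / (4 ** k * 4 ** k * n_bins)
    if epsilon <= 0:
        raise TrainingError("epsilon must be positive")
    fp = _class_frequencies(pos, scheme, k, n_bins)
    fn = _class_frequencies(neg, scheme, k, n_bins)
    entries = -np.log((fp + epsilon) / (fn + epsilon))
    return PotentialTable(
        scheme=scheme, k=k, n_bins=n_bins, entries=entries,
        epsilon=epsilon, provenance=_fingerprint(pos, neg, scheme, k, n_bins),
    )


def score_distance_specific(seq: Sequence, table: PotentialTable) -> float:
    """Mean table energy over all ordered k-mer pairs of ``seq`` (0 if none)."""
    if table.scheme != "distance_specific":
        raise ValueError("table is not distance-specific")
    wa, wb, bb = _pair_events(seq, table.k, table.n_bins, relative_distance=False)
    if len(wa) == 0:
        return 0.0
    return float(table.entries[wa, wb, bb].mean())


def score_position_specific(
    seq: Sequence, ss: SecondaryStructure, table: PotentialTable
) -> np.ndarray:
    """Per-bin mean contact energy: 34 values, 0 for bins with no contact."""
    if table.scheme != "position_specific":
        raise ValueError("table is not position-specific")
    n_bins = table.n_bins
    wa, wb, bb = _contact_events(seq, ss, n_bins)
    out = np.zeros(n_bins, dtype=np.float64)
    if len(wa) == 0:
        return out
    energies = table.entries[wa, wb, bb]
    sums = np.bincount(bb, weights=energies, minlength=n_bins)
    counts = np.bincount(bb, minlength=n_bins)
    occupied = counts > 0
    out[occupied] = sums[occupied] / counts[occupied]
    return out


def score_distance_dependent(seq: Sequence, tables: dict) -> np.ndarray:
    """26 values: 20 pooled per-bin means, 3 per-k means, 3 per-k std devs.

    ``tables`` maps k in {1, 2, 3} to a trained distance-dependent table.
    Per-bin scores pool the energies of all three k values falling in the
    bin (0 for an empty bin); the per-k mean is over all of that k's pairs;
    the per-k standard deviation is the population std of that k's occupied
    per-bin means (0 when fewer than one bin is occupied).
    """
    n_bins = DISTANCE_DEPENDENT_BINS
    pooled_sums = np.zeros(n_bins)
    pooled_counts = np.zeros(n_bins)
    per_k_mean = []
    per_k_std = []
    for k in DISTANCE_DEPENDENT_KS:
        table = tables[k]
        if table.scheme != "distance_dependent" or table.n_bins != n_bins:
            raise ValueError(f"table for k={k} is not distance-dependent/20-bin")
        wa, wb, bb = _pair_events(seq, k, n_bins, relative_distance=True)
        if len(wa) == 0:
            per_k_mean.append(0.0)
            per_k_std.append(0.0)
            continue
        energies = table.entries[wa, wb, bb]
        sums = np.bincount(bb, weights=energies, minlength=n_bins)
        counts = np.bincount(bb, minlength=n_bins)
        pooled_sums += sums
        pooled_counts += counts
        occupied = counts > 0
        bin_means = sums[occupied] / counts[occupied]
        per_k_mean.append(float(energies.mean()))
        per_k_std.append(float(bin_means.std()) if bin_means.size else 0.0)
    bin_scores = np.zeros(n_bins)
    occ = pooled_counts > 0
    bin_scores[occ] = pooled_sums[occ] / pooled_counts[occ]
    return np.concatenate([bin_scores, per_k_mean, per_k_std])


@dataclass(frozen=True)
class PotentialSet:
    """The full bundle of trained tables the featurizer needs."""

    position_specific: PotentialTable
    distance_specific: dict       # k (1..5) -> PotentialTable
    distance_dependent: dict      # k (1..3) -> PotentialTable

    @classmethod
    def train(cls, pos, neg, epsilon: float | None = None) -> "PotentialSet":
        """Train every table scheme on the same labelled structure sets."""
        return cls(
            position_specific=train_potentials(
                pos, neg, "position_specific", k=2, n_bins=POSITION_BINS,
                epsilon=epsilon,
            ),
            distance_specific={
                k: train_potentials(
                    pos, neg, "distance_specific", k=k, n_bins=1,
                    epsilon=epsilon,
                )
                for k in DISTANCE_SPECIFIC_KS
            },
            distance_dependent={
                k: train_potentials(
                    pos, neg, "distance_dependent", k=k,
                    n_bins=DISTANCE_DEPENDENT_BINS, epsilon=epsilon,
                )
                for k in DISTANCE_DEPENDENT_KS
            },
        )

    @classmethod
    def zeros(cls) -> "PotentialSet":
        """All-zero tables (every feature neutral); useful for testing."""
        def z(scheme, k, n_bins):
            return PotentialTable(
                scheme=scheme, k=k, n_bins=n_bins,
                entries=np.zeros((4 ** k, 4 ** k, n_bins)),
                epsilon=1.0, provenance="zeros",
            )
        return cls(
            position_specific=z("position_specific", 2, POSITION_BINS),
            distance_specific={k: z("distance_specific", k, 1)
                               for k in DISTANCE_SPECIFIC_KS},
            distance_dependent={k: z("distance_dependent", k,
                                     DISTANCE_DEPENDENT_BINS)
                                for k in DISTANCE_DEPENDENT_KS},
        )
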