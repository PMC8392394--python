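"""Sequence-composition and thermodynamic-ratio feature blocks.

Composition covers GC content, overlapping dinucleotide percentages and
2-/3-mer frequencies; the thermodynamic block combines the structure's
energy with the element counts from :mod:`mirhairpin.structure` into the
classical normalized ratios (dG = MFE/L, dP = pairs/L, per-stem averages,
and so on).  Any ratio whose denominator is zero — no stems, no loops, no
bulges, no pairs, GC content zero — is emitted as 0 and the feature name is
recorded in the block's ``warnings``, so hairpin-less candidates remain
scoreable rather than fatal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import TooShortError
from .io_seq import Sequence
from .folding import SecondaryStructure
from .structure import StructureElements

ALPHABET = "ACGU"


def kmer_names(k: int) -> list[str]:
    """All length-k words in lexicographic order (A < C < G < U)."""
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


@dataclass(frozen=True)
class FeatureBlock:
    """An ordered, named block of real-valued features."""

    names: tuple
    values: tuple
    warnings: frozenset = field(default=frozenset())

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names in block")

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def _window_counts(s: str, k: int) -> dict:
    counts = {w: 0 for w in kmer_names(k)}
    for i in range(len(s) - k + 1):
        counts[s[i : i + k]] += 1
    return counts


def gc_percent(seq: Sequence) -> float:
    s = seq.residues
    return (s.count("G") + s.count("C")) / len(s) * 100.0


def composition_block(seq: Sequence) -> FeatureBlock:
    """GC%, 16 dinucleotide percentages and 80 k-mer frequencies (k=2,3).

    Dinucleotide %XY = |XY| / (L-1) * 100 over overlapping windows; k-mer
    frequencies are overlapping counts normalized by L-k+1.  Requires L >= 3.
    """
    L = len(seq)
    if L < 3:
        raise TooShortError(f"record {seq.id!r}: length {L} < 3")
    s = seq.residues
    names: list[str] = ["pct_G+C"]
    values: list[float] = [gc_percent(seq)]
    di = _window_counts(s, 2)
    for w in kmer_names(2):
        names.append(f"pct_{w}")
        values.append(di[w] / (L - 1) * 100.0)
    for w in kmer_names(2):
        names.append(f"freq2_{w}")
        values.append(di[w] / (L - 1))
    tri = _window_counts(s, 3)
    for w in kmer_names(3):
        names.append(f"freq3_{w}")
        values.append(tri[w] / (L - 2))
    return FeatureBlock(names=tuple(names), values=tuple(values))


def _safe_div(num: float, den: float, name: str, warnings: set) -> float:
    if den == 0:
        warnings.add(name)
        return 0.0
    return num / den


def thermo_pairing_block(
    seq: Sequence,
    ss: SecondaryStructure,
    elems: StructureElements,
    stem_pct_reading: str = "literal",
) -> FeatureBlock:
    """The 18 energy/pairing ratios built on MFE and the element counts.

    ``stem_pct_reading`` selects how the three per-pair-type "percentage per
    stem" features are computed:

    * ``"literal"`` (default): %(X-Y) = |X-Y| / n_stems * 100 and the feature
      is %(X-Y) / n_stems, i.e. |X-Y| * 100 / n_stems**2.
    * ``"per_pairs"``: the microPred-style reading,
      (|X-Y| / tot_bases * 100) / n_stems.
    """
    if stem_pct_reading not in ("literal", "per_pairs"):
        raise ValueError(f"unknown stem_pct_reading {stem_pct_reading!r}")
    L = len(seq)
    mfe = ss.mfe if ss.mfe is not None else 0.0
    warnings: set = set()
    gc = gc_percent(seq)
    dG = mfe / L
    n_stems = elems.n_stems
    n_loops = elems.n_loops
    n_bulges = elems.n_bulges
    tot = elems.tot_bases

    names: list[str] = []
    values: list[float] = []

    def put(name: str, value: float) -> None:
        names.append(name)
        values.append(value)

    put("dG", dG)
    put("MFE1", _safe_div(dG, gc, "MFE1", warnings))
    put("MFE2", _safe_div(dG, n_stems, "MFE2", warnings))
    put("dP", tot / L)
    put("MFE3", _safe_div(dG, n_loops, "MFE3", warnings))
    for t in ("AU", "GC", "GU"):
        put(f"bp_{t}_per_L", elems.pairs_by_type[t] / L)
    for t in ("AU", "GC", "GU"):
        count = elems.pairs_by_type[t]
        name = f"pct_bp_{t}_per_stems"
        if stem_pct_reading == "literal":
            pct = _safe_div(count * 100.0, n_stems, name, warnings)
        else:
            pct = _safe_div(count * 100.0, tot, name, warnings)
        put(name, _safe_div(pct, n_stems, name, warnings))
    put("avg_bp_stem1", _safe_div(tot, n_stems, "avg_bp_stem1", warnings))
    put("pb_per_nb", _safe_div(elems.pb, elems.nb, "pb_per_nb", warnings))
    put("MCPN", float(elems.mcpn))
    put("n_bulges_per_L", n_bulges / L)
    put("avg_bp_stem2", _safe_div(elems.pb, n_stems, "avg_bp_stem2", warnings))
    put("MFE4", _safe_div(dG, tot, "MFE4", warnings))
    put("MFE5", _safe_div(dG, n_bulges, "MFE5", warnings))

    return FeatureBlock(
        names=tuple(names), values=tuple(values), warnings=frozenset(warnings)
    )
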