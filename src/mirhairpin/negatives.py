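"""Pseudo pre-miRNA construction from coding sequence.

Negative training examples must look enough like genuine precursors that the
classifier learns something harder than "hairpin vs not".  Windows are cut
from CDS records at lengths drawn from the positive set's empirical length
distribution, T->U converted, folded, and kept only when they resemble the
positive set structurally:

(a) at least one stem (>= 3 stacked pairs);
(b) pairing density dP = pairs/L inside the positive set's observed range;
(c) energy density dG = MFE/L inside the positive set's observed range.

Windows never overlap a previously accepted window of the same source
record, so near-duplicate negatives are avoided.  Sampling is reproducible
under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import TrainingError
from .folding import fold
from .io_seq import Sequence
from .structure import decompose

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LengthSampler:
    """Empirical length distribution of a positive set."""

    lengths: tuple

    @classmethod
    def from_positives(cls, positives) -> "LengthSampler":
        lengths = tuple(len(p) for p in positives)
        if not lengths:
            raise TrainingError("length sampler needs at least one positive")
        return cls(lengths=lengths)

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.lengths))


@dataclass(frozen=True)
class PseudoFilter:
    """Similarity filters a pseudo hairpin must pass."""

    min_dp: float
    max_dp: float
    min_dg: float
    max_dg: float
    require_stem: bool = True

    @classmethod
    def from_positives(cls, pos_pairs, trim_pct: float = 0.0) -> "PseudoFilter":
        """Ranges from a folded positive set; ``trim_pct`` (0-50) optionally
        trims each tail to the given percentile."""
        dps, dgs = [], []
        for seq, ss in pos_pairs:
            elems = decompose(seq, ss)
            dps.append(elems.tot_bases / len(seq))
            dgs.append((ss.mfe or 0.0) / len(seq))
        if not dps:
            raise TrainingError("filter needs at least one folded positive")
        lo, hi = trim_pct, 100.0 - trim_pct
        return cls(
            min_dp=float(np.percentile(dps, lo)),
            max_dp=float(np.percentile(dps, hi)),
            min_dg=float(np.percentile(dgs, lo)),
            max_dg=float(np.percentile(dgs, hi)),
        )

    def accept(self, seq: Sequence, ss) -> bool:
        elems = decompose(seq, ss)
        if self.require_stem and elems.n_stems < 1:
            return False
        dp = elems.tot_bases / len(seq)
        if not (self.min_dp <= dp <= self.max_dp):
            return False
        dg = (ss.mfe or 0.0) / len(seq)
        return self.min_dg <= dg <= self.max_dg


def extract_pseudo_hairpins(
    cds: list[Sequence],
    n_wanted: int,
    length_sampler: LengthSampler,
    filters: PseudoFilter,
    seed: int = 0,
    engine: str = "auto",
    max_attempts: int | None = None,
) -> list[Sequence]:
    """Sample filtered pseudo-hairpin windows from CDS records.

    Returns up to ``n_wanted`` windows; if the attempt budget (default
    ``60 * n_wanted``) runs out first, fewer are returned with a logged
    warning.  Window ids carry provenance: ``<source>|<start>-<end>``
    (1-based inclusive coordinates into the source record).
    """
    if not cds:
        raise TrainingError("CDS set is empty")
    rng = np.random.default_rng(seed)
    if max_attempts is None:
        max_attempts = 60 * n_wanted
    taken: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(cds))}
    out: list[Sequence] = []
    attempts = 0
    while len(out) < n_wanted and attempts < max_attempts:
        attempts += 1
        src_idx = int(rng.integers(len(cds)))
        src = cds[src_idx]
        w = length_sampler.sample(rng)
        if w > len(src) or w < 10:
            continue
        start = int(rng.integers(len(src) - w + 1)) + 1  # 1-based
        end = start + w - 1
        if any(s <= end and start <= e for s, e in taken[src_idx]):
            continue
        window = Sequence(
            id=f"{src.id}|{start}-{end}",
            residues=src.residues[start - 1 : end],
        )
        ss = fold(window, engine=engine)
        if not filters.accept(window, ss):
            continue
        taken[src_idx].append((start, end))
        out.append(window)
    if len(out) < n_wanted:
        logger.warning(
            "extract_pseudo_hairpins: produced %d of %d windows after %d attempts",
            len(out), n_wanted, attempts,
        )
    return out
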