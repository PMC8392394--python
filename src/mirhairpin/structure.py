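"""Decomposition of a secondary structure into stems, loops and bulges.

Definitions used throughout (these parameterize the structural features):

* **stem** — a maximal run of consecutively stacked pairs
  (i, j), (i+1, j-1), ... of length >= 3 pairs.  A single unpaired position
  on either strand ends the run; two helices split by a 1-nt bulge are two
  candidate stems, each needing >= 3 pairs to count.
* **loop** — a maximal run of unpaired positions enclosed by at least one
  pair (hairpin, interior and bulge loops all count; external unpaired
  tails do not).
* **bulge** — a maximal run of >= 3 adjacent unpaired nucleotides anywhere
  in the structure, terminal loop included.  ``include_hairpin_loop=False``
  gives the classical reading that excludes the hairpin loop.
* **MCPN** — the maximum number of consecutive paired sequence positions
  (bracket characters), not stacked pairs: ``((((....))))`` gives 4.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import TooShortError
from .folding import SecondaryStructure
from .io_seq import Sequence

MIN_STEM_PAIRS = 3
MIN_BULGE_NT = 3


@dataclass(frozen=True)
class StructureElements:
    """Structural element counts for one (sequence, structure) pair."""

    n_stems: int
    n_loops: int
    n_bulges: int
    tot_bases: int          # number of base pairs
    pb: int                 # paired positions (2 * tot_bases)
    nb: int                 # unpaired positions
    biggest_bulge: int      # size of the largest bulge (0 if none)
    mcpn: int               # max run of consecutive paired positions
    pairs_by_type: dict     # {"AU": ..., "GC": ..., "GU": ...}


def _unpaired_runs(db: str) -> list[tuple[int, int]]:
    """Maximal runs of '.' as 1-based inclusive (start, end)."""
    runs = []
    start = None
    for pos, ch in enumerate(db, start=1):
        if ch == ".":
            if start is None:
                start = pos
        else:
            if start is not None:
                runs.append((start, pos - 1))
                start = None
    if start is not None:
        runs.append((start, len(db)))
    return runs


def _stem_runs(pairs: frozenset) -> list[int]:
    """Lengths of maximal stacked-pair runs."""
    if not pairs:
        return []
    ordered = sorted(pairs)
    pairset = set(pairs)
    runs = []
    seen = set()
    for i, j in ordered:
        if (i, j) in seen:
            continue
        length = 0
        a, b = i, j
        while (a, b) in pairset:
            seen.add((a, b))
            length += 1
            a, b = a + 1, b - 1
        runs.append(length)
    return runs


def decompose(
    seq: Sequence,
    ss: SecondaryStructure,
    include_hairpin_loop: bool = True,
) -> StructureElements:
    """Count stems, loops, bulges and pairing statistics.

    ``include_hairpin_loop`` controls whether the terminal (hairpin) loop can
    qualify as a bulge; the default follows the literal ">= 3 adjacent
    unpaired nucleotides" reading.
    """
    if len(ss) != len(seq):
        raise ValueError(
            f"structure length {len(ss)} != sequence length {len(seq)}"
        )
    db = ss.dotbracket
    L = len(seq)
    pairs = ss.pairs
    tot_bases = len(pairs)
    pb = 2 * tot_bases
    nb = L - pb

    stem_lengths = _stem_runs(pairs)
    n_stems = sum(1 for s in stem_lengths if s >= MIN_STEM_PAIRS)

    runs = _unpaired_runs(db)

    # depth before a run's start > 0  <=>  some pair encloses the whole run
    # (holds because positions inside the run are all unpaired)
    depth = 0
    depth_before = {}
    for pos, ch in enumerate(db, start=1):
        depth_before[pos] = depth
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
    n_loops = sum(1 for a, _ in runs if depth_before[a] > 0)

    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    def is_hairpin_loop(a: int, b: int) -> bool:
        return (
            a > 1 and b < L
            and partner.get(a - 1) == b + 1
        )

    bulge_sizes = []
    for a, b in runs:
        size = b - a + 1
        if size < MIN_BULGE_NT:
            continue
        if not include_hairpin_loop and is_hairpin_loop(a, b):
            continue
        bulge_sizes.append(size)
    n_bulges = len(bulge_sizes)
    biggest_bulge = max(bulge_sizes, default=0)

    mcpn = 0
    run = 0
    for ch in db:
        if ch != ".":
            run += 1
            mcpn = max(mcpn, run)
        else:
            run = 0

    by_type = {"AU": 0, "GC": 0, "GU": 0}
    for i, j in pairs:
        key = "".join(sorted((seq.residues[i - 1], seq.residues[j - 1])))
        if key == "AU":
            by_type["AU"] += 1
        elif key == "CG":
            by_type["GC"] += 1
        elif key == "GU":
            by_type["GU"] += 1
        # non-canonical pairs in a provided structure are not typed

    return StructureElements(
        n_stems=n_stems, n_loops=n_loops, n_bulges=n_bulges,
        tot_bases=tot_bases, pb=pb, nb=nb,
        biggest_bulge=biggest_bulge, mcpn=mcpn, pairs_by_type=by_type,
    )


def unpaired_region_ratios(seq: Sequence, ss: SecondaryStructure) -> list[float]:
    """Fraction of unpaired positions in each of 10 contiguous sub-regions.

    Positions 1..L are cut into 10 contiguous regions of size floor(L/10) or
    ceil(L/10); the first ``L mod 10`` regions get the extra position.  Each
    ratio is (unpaired positions in region) / (region size), in [0, 1].
    """
    L = len(seq)
    if L < 10:
        raise TooShortError(f"record {seq.id!r}: length {L} < 10")
    if len(ss) != L:
        raise ValueError("structure does not belong to sequence")
    base, rem = divmod(L, 10)
    ratios = []
    pos = 0  # 0-based cursor into the dot-bracket
    for r in range(10):
        size = base + (1 if r < rem else 0)
        region = ss.dotbracket[pos : pos + size]
        ratios.append(region.count(".") / size)
        pos += size
    return ratios
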