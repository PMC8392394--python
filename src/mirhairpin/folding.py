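"""Secondary-structure prediction for hairpin candidates.

Every downstream feature depends on a single minimum-free-energy structure.
Two engines are provided behind one interface:

* ``vienna`` — the ViennaRNA thermodynamic model, used through the ``RNA``
  python bindings when importable, otherwise through the ``RNAfold``
  executable.  This is the engine real analyses should use.
* ``fallback`` — a self-contained base-pair-maximization dynamic program
  (Nussinov-style) with pair weights GC=3, AU=2, GU=1 and a minimum hairpin
  loop of 3 nt.  Its "mfe" is the negated pairing score, a dimensionless
  pseudo-energy.  It exists so the whole pipeline runs with no external
  thermodynamics and so folding can be checked against exhaustive
  enumeration at small lengths.

``auto`` tries vienna and falls back with a logged warning.  Among co-optimal
fallback structures the one whose sorted pair list is lexicographically
smallest is returned, which makes the fallback deterministic and directly
comparable to a brute-force oracle.
"""

from __future__ import annotations

import functools
import logging
import shutil
import subprocess
from dataclasses import dataclass, field

from .errors import EngineUnavailableError, StructureError, TooShortError
from .io_seq import Sequence

logger = logging.getLogger(__name__)

MIN_FOLD_LENGTH = 10
MIN_LOOP = 3  # unpaired nt enclosed by a hairpin-closing pair

#: canonical pair weights for the fallback scorer
PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}

CANONICAL_PAIRS = frozenset(PAIR_WEIGHT)


def parse_dotbracket(db: str) -> set[tuple[int, int]]:
    """Stack-match a dot-bracket string into a set of 1-based (i, j) pairs."""
    if set(db) - set("()."):
        raise StructureError(f"invalid characters in dot-bracket: {db!r}")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def render_dotbracket(pairs: set[tuple[int, int]], length: int) -> str:
    """Inverse of :func:`parse_dotbracket` for a nested pair set."""
    chars = ["."] * length
    for i, j in pairs:
        if not (1 <= i < j <= length):
            raise StructureError(f"pair ({i},{j}) outside 1..{length}")
        if chars[i - 1] != "." or chars[j - 1] != ".":
            raise StructureError(f"position reused by pair ({i},{j})")
        chars[i - 1] = "("
        chars[j - 1] = ")"
    db = "".join(chars)
    # round-trip validates nestedness
    if parse_dotbracket(db) != set(pairs):
        raise StructureError("pair set is not nested")
    return db


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested (pseudoknot-free) secondary structure.

    ``pairs`` are 1-based (i, j) with i < j; ``mfe`` is the engine's free
    energy in kcal/mol (or the fallback pseudo-energy); ``source`` records
    where the structure came from: ``engine``, ``fallback`` or ``provided``.
    """

    dotbracket: str
    pairs: frozenset = field(default=frozenset())
    mfe: float | None = None
    source: str = "provided"

    @classmethod
    def from_dotbracket(
        cls, db: str, mfe: float | None = None, source: str = "provided"
    ) -> "SecondaryStructure":
        return cls(dotbracket=db, pairs=frozenset(parse_dotbracket(db)),
                   mfe=mfe, source=source)

    def __len__(self) -> int:
        return len(self.dotbracket)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _pair_weight(a: str, b: str) -> int:
    return PAIR_WEIGHT.get((a, b), 0)


def nussinov_fold(residues: str) -> tuple[set[tuple[int, int]], int]:
    """Weighted base-pair maximization with deterministic tie-breaking.

    Returns the optimal pair set (1-based) and its integer score.  Among
    co-optimal structures the sorted pair list that is lexicographically
    smallest is chosen; this matches an exhaustive-enumeration oracle using
    the same tie rule.
    """
    n = len(residues)
    # W[i][j]: best score on the 0-based inclusive interval [i, j]
    W = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i + 1][j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                w = _pair_weight(residues[i], residues[k])
                if w == 0:
                    continue
                inner = W[i + 1][k - 1] if k - 1 > i + 1 else 0
                right = W[k + 1][j] if k + 1 < j else (0 if k + 1 > j else W[k + 1][j])
                s = w + inner + right
                if s > best:
                    best = s
            W[i][j] = best

    @functools.lru_cache(maxsize=None)
    def best_pairs(i: int, j: int) -> tuple[tuple[int, int], ...]:
        if j - i < MIN_LOOP + 1 or i >= j:
            return ()
        target = W[i][j]
        candidates = []
        if W[i + 1][j] == target:
            candidates.append(best_pairs(i + 1, j))
        for k in range(i + MIN_LOOP + 1, j + 1):
            w = _pair_weight(residues[i], residues[k])
            if w == 0:
                continue
            inner = W[i + 1][k - 1] if k - 1 >= i + 1 else 0
            right = W[k + 1][j] if k + 1 <= j else 0
            if w + inner + right == target:
                candidates.append(
                    ((i + 1, k + 1),)
                    + best_pairs(i + 1, k - 1)
                    + best_pairs(k + 1, j)
                )
        return min(candidates)

    if n == 0:
        return set(), 0
    pairs = set(best_pairs(0, n - 1))
    score = W[0][n - 1]
    best_pairs.cache_clear()
    return pairs, score


def _fold_fallback(seq: Sequence) -> SecondaryStructure:
    pairs, score = nussinov_fold(seq.residues)
    db = render_dotbracket(pairs, len(seq))
    return SecondaryStructure(
        dotbracket=db, pairs=frozenset(pairs), mfe=-float(score),
        source="fallback",
    )


def _vienna_available() -> bool:
    try:
        import RNA  # noqa: F401
        return True
    except ImportError:
        return shutil.which("RNAfold") is not None


def _fold_vienna(seq: Sequence) -> SecondaryStructure:
    try:
        import RNA
    except ImportError:
        RNA = None
    if RNA is not None:
        db, mfe = RNA.fold(seq.residues)
    else:
        exe = shutil.which("RNAfold")
        if exe is None:
            raise EngineUnavailableError("ViennaRNA not available")
        proc = subprocess.run(
            [exe, "--noPS"], input=f">{seq.id}\n{seq.residues}\n",
            capture_output=True, text=True, check=True,
        )
        lines = proc.stdout.strip().splitlines()
        struct_line = lines[-1]
        db = struct_line.split()[0]
        mfe = float(struct_line[struct_line.rfind("(") + 1 : struct_line.rfind(")")])
    return SecondaryStructure(
        dotbracket=db, pairs=frozenset(parse_dotbracket(db)),
        mfe=float(mfe), source="engine",
    )


def fold(seq: Sequence, engine: str = "auto") -> SecondaryStructure:
    """Predict the MFE structure of ``seq`` with the selected engine.

    Parameters
    ----------
    seq : Sequence
        RNA sequence, at least 10 nt (shorter cannot form the minimal
        hairpin).
    engine : {"auto", "vienna", "fallback"}
        ``auto`` uses ViennaRNA when available and otherwise falls back to
        the internal weighted Nussinov scorer with a logged warning.
    """
    if len(seq) < MIN_FOLD_LENGTH:
        raise TooShortError(
            f"record {seq.id!r}: length {len(seq)} < {MIN_FOLD_LENGTH}"
        )
    if engine == "fallback":
        return _fold_fallback(seq)
    if engine == "vienna":
        if not _vienna_available():
            raise EngineUnavailableError("ViennaRNA engine requested but not found")
        return _fold_vienna(seq)
    if engine == "auto":
        if _vienna_available():
            return _fold_vienna(seq)
        logger.warning("ViennaRNA unavailable; using the internal fallback scorer")
        return _fold_fallback(seq)
    raise ValueError(f"unknown engine {engine!r}")


def fold_many(
    seqs: list[Sequence], engine: str = "auto"
) -> list[tuple[Sequence, SecondaryStructure]]:
    """Fold a batch, preserving order."""
    return [(s, fold(s, engine=engine)) for s in seqs]
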