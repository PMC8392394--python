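"""Reading and writing RNA sequence and secondary-structure files.

Sequences are RNA records over the strict alphabet {A, C, G, U}.  On input,
lowercase is uppercased and DNA-style T is mapped to U (miRBase distributes
RNA, genome-derived CDS comes as DNA); any record that still contains a
character outside the alphabet — including IUPAC ambiguity codes such as N —
is either dropped with a logged count or rejected, depending on policy.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, StructureError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

_MFE_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


@dataclass(frozen=True)
class Sequence:
    """A validated RNA sequence record.

    Attributes
    ----------
    id : str
        Record identifier (FASTA header word).
    residues : str
        Uppercase RNA string over {A, C, G, U}.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-AUCG characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Uppercase and map T->U.  Does not validate."""
    return raw.upper().replace("T", "U")


def is_valid_rna(raw: str) -> bool:
    s = normalize_residues(raw)
    return len(s) >= 1 and set(s) <= RNA_ALPHABET


def read_fasta(
    path: str | Path,
    policy: Literal["drop_invalid", "error"] = "drop_invalid",
) -> list[Sequence]:
    """Read a FASTA file into validated :class:`Sequence` records.

    T/t are mapped to U, lowercase is uppercased.  Records still containing
    non-AUCG characters are dropped (``policy="drop_invalid"``, with the
    count logged) or raise a :class:`FormatError` (``policy="error"``).
    Record order is preserved.  An empty file yields an empty list.
    """
    if policy not in ("drop_invalid", "error"):
        raise ValueError(f"unknown policy {policy!r}")
    records: list[Sequence] = []
    n_dropped = 0
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython rejects body-before-header etc.
        raise FormatError(f"{path}: malformed FASTA: {exc}") from exc
    for rec in parsed:
        residues = normalize_residues(str(rec.seq))
        if len(residues) >= 1 and set(residues) <= RNA_ALPHABET:
            records.append(Sequence(id=rec.id, residues=residues))
        elif policy == "error":
            raise FormatError(f"record {rec.id!r}: non-AUCG characters")
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("read_fasta(%s): dropped %d record(s) with non-AUCG characters",
                    path, n_dropped)
    return records


def write_fasta(records: Iterable[Sequence], path: str | Path) -> None:
    """Write records as multi-FASTA, 60-column wrapped."""
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def deduplicate(records: Iterable[Sequence]) -> list[Sequence]:
    """Drop exact-duplicate residue strings, keeping the first occurrence.

    Optional filter: cross-species miRBase entries can share identical
    precursor sequences; this is not applied by default anywhere.
    """
    seen: set[str] = set()
    out = []
    for r in records:
        if r.residues not in seen:
            seen.add(r.residues)
            out.append(r)
    return out


def read_vienna(path: str | Path) -> list[tuple[Sequence, "SecondaryStructure"]]:
    """Read a Vienna dot-bracket file (header / sequence / structure triplets).

    The structure line may end with the minimum free energy in parentheses,
    e.g. ``(((...))) (-1.30)``; when absent the structure's ``mfe`` is None.
    Structures are tagged ``source="provided"`` so downstream featurization
    knows folding was bypassed.
    """
    from .folding import SecondaryStructure  # local import avoids a cycle

    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    out: list[tuple[Sequence, SecondaryStructure]] = []
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise FormatError(f"{path}: expected '>' header at line {i + 1}")
        if i + 2 >= len(lines):
            raise FormatError(f"{path}: truncated record {header!r}")
        residues = normalize_residues(lines[i + 1].strip())
        struct_line = lines[i + 2].strip()
        m = _MFE_RE.search(struct_line)
        if m:
            mfe: float | None = float(m.group(1))
            db = struct_line[: m.start()].strip()
        else:
            mfe = None
            db = struct_line
        if set(db) - set("().") :
            raise FormatError(f"{path}: bad structure characters in {header!r}")
        if len(db) != len(residues):
            raise FormatError(
                f"{path}: structure length {len(db)} != sequence length "
                f"{len(residues)} in {header!r}"
            )
        seq = Sequence(id=header[1:].split()[0], residues=residues)
        ss = SecondaryStructure.from_dotbracket(db, mfe=mfe, source="provided")
        out.append((seq, ss))
        i += 3
    return out


def write_vienna(
    items: Iterable[tuple[Sequence, "SecondaryStructure"]], path: str | Path
) -> None:
    """Write (sequence, structure) pairs in Vienna dot-bracket form."""
    with open(path, "w") as fh:
        for seq, ss in items:
            fh.write(f">{seq.id}\n{seq.residues}\n{ss.dotbracket}")
            if ss.mfe is not None:
                fh.write(f" ({ss.mfe:.2f})")
            fh.write("\n")
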