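"""Reference dataset composition for the published plant pre-miRNA corpus.

Per-species positive training counts for the nine major plant species drawn
from miRBase release 22.1 (sequences with non-AUCG characters removed), the
positive testing count from the remaining species, and the CDS-derived
pseudo-hairpin negative split.  These document the training conditions the
classifier design targets; the package's own tests and benchmarks run on
synthetic data of the same shape.
"""

from __future__ import annotations

#: miRBase release 22.1 positive training counts, nine major plant species
TRAINING_COUNTS_22_1 = {
    "Arabidopsis thaliana": 326,
    "Glycine max": 684,
    "Oryza sativa": 604,
    "Physcomitrella patens": 247,
    "Medicago truncatula": 672,
    "Sorghum bicolor": 205,
    "Arabidopsis lyrata": 205,
    "Zea mays": 168,
    "Solanum lycopersicum": 112,
}

#: positive testing set: remaining plant species in release 22.1
POSITIVE_TESTING_TOTAL_22_1 = 5323

#: CDS-derived pseudo pre-miRNA negatives and their train/test split
NEGATIVE_TRAINING_TOTAL = 5186
NEGATIVE_TESTING_TOTAL = 3466


def positive_training_total() -> int:
    """Sum of the nine per-species training counts."""
    return sum(TRAINING_COUNTS_22_1.values())


def negative_total() -> int:
    """Total pseudo-hairpin negatives (training + testing)."""
    return NEGATIVE_TRAINING_TOTAL + NEGATIVE_TESTING_TOTAL
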