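"""Assembly of the full ordered 193-dimensional feature vector.

Vector layout (block sizes sum to 193, asserted at import):

====  ====================================================================
size  block
====  ====================================================================
 34   position-specific 2-mer contact potentials (per-position-bin means)
  5   distance-specific k-mer pair potentials, k = 1..5
 10   unpaired-nucleotide ratio in 10 sequence sub-regions
  4   biggest bulge, n_stems/L, n_loops/L, GC%
 16   dinucleotide percentages %XY
  5   dG, MFE1, MFE2, dP, MFE3
  3   base-pair fractions |X-Y|/L for AU, GC, GU
  3   %(X-Y)/n_stems for AU, GC, GU
  7   avg_bp_stem1, pb/nb, MCPN, n_bulges/L, avg_bp_stem2, MFE4, MFE5
 80   k-mer frequencies, k = 2 and 3
 26   distance-dependent k-mer pair potentials (20 bins + per-k mean/std)
====  ====================================================================

Feature names and order are frozen in a versioned manifest; a trained model
refuses matrices produced under a different manifest version, so silent
column drift across releases is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import composition_block, kmer_names, thermo_pairing_block
from .errors import ConfigurationError, FormatError
from .folding import SecondaryStructure
from .io_seq import Sequence
from .potentials import (
    DISTANCE_DEPENDENT_BINS,
    DISTANCE_DEPENDENT_KS,
    DISTANCE_SPECIFIC_KS,
    POSITION_BINS,
    PotentialSet,
    score_distance_dependent,
    score_distance_specific,
    score_position_specific,
)
from .structure import decompose, unpaired_region_ratios

MANIFEST_VERSION = "mirhairpin-features-1"

BLOCK_SIZES = (34, 5, 10, 4, 16, 5, 3, 3, 7, 80, 26)
N_FEATURES = 193
assert sum(BLOCK_SIZES) == N_FEATURES


def _build_names() -> tuple:
    names: list[str] = []
    names += [f"pos2mer_pot_bin{b}" for b in range(1, POSITION_BINS + 1)]
    names += [f"dist_pot_k{k}" for k in DISTANCE_SPECIFIC_KS]
    names += [f"unpaired_ratio_region{r}" for r in range(1, 11)]
    names += ["biggest_bulge", "n_stems_per_L", "n_loops_per_L", "pct_G+C"]
    names += [f"pct_{w}" for w in kmer_names(2)]
    names += ["dG", "MFE1", "MFE2", "dP", "MFE3"]
    names += [f"bp_{t}_per_L" for t in ("AU", "GC", "GU")]
    names += [f"pct_bp_{t}_per_stems" for t in ("AU", "GC", "GU")]
    names += ["avg_bp_stem1", "pb_per_nb", "MCPN", "n_bulges_per_L",
              "avg_bp_stem2", "MFE4", "MFE5"]
    names += [f"freq2_{w}" for w in kmer_names(2)]
    names += [f"freq3_{w}" for w in kmer_names(3)]
    names += [f"dd_pot_bin{b}" for b in range(1, DISTANCE_DEPENDENT_BINS + 1)]
    names += [f"dd_pot_mean_k{k}" for k in DISTANCE_DEPENDENT_KS]
    names += [f"dd_pot_std_k{k}" for k in DISTANCE_DEPENDENT_KS]
    return tuple(names)


FEATURE_NAMES = _build_names()
assert len(FEATURE_NAMES) == N_FEATURES
assert len(set(FEATURE_NAMES)) == N_FEATURES


@dataclass(frozen=True)
class FeatureVector:
    """One sequence's 193 ordered feature values."""

    id: str
    values: np.ndarray
    warnings: frozenset = field(default=frozenset())

    def __post_init__(self) -> None:
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values for {self.id!r}")


def featurize(
    seq: Sequence,
    ss: SecondaryStructure,
    tables: PotentialSet,
    stem_pct_reading: str = "literal",
) -> FeatureVector:
    """Compute the full feature vector for one folded (or provided) hairpin.

    A pure function of (residues, dot-bracket, mfe, tables); requires
    trained potential tables and a structure of the sequence's length.
    """
    if tables is None:
        raise ConfigurationError("potential tables are required")
    if len(ss) != len(seq):
        raise ValueError("structure does not belong to sequence")
    L = len(seq)
    elems = decompose(seq, ss)
    comp = composition_block(seq).as_dict()
    thermo = thermo_pairing_block(seq, ss, elems, stem_pct_reading=stem_pct_reading)
    thermo_d = thermo.as_dict()

    parts = [
        score_position_specific(seq, ss, tables.position_specific),
        np.array([
            score_distance_specific(seq, tables.distance_specific[k])
            for k in DISTANCE_SPECIFIC_KS
        ]),
        np.array(unpaired_region_ratios(seq, ss)),
        np.array([
            float(elems.biggest_bulge),
            elems.n_stems / L,
            elems.n_loops / L,
            comp["pct_G+C"],
        ]),
        np.array([comp[f"pct_{w}"] for w in kmer_names(2)]),
        np.array([thermo_d[n] for n in ("dG", "MFE1", "MFE2", "dP", "MFE3")]),
        np.array([thermo_d[f"bp_{t}_per_L"] for t in ("AU", "GC", "GU")]),
        np.array([thermo_d[f"pct_bp_{t}_per_stems"] for t in ("AU", "GC", "GU")]),
        np.array([thermo_d[n] for n in (
            "avg_bp_stem1", "pb_per_nb", "MCPN", "n_bulges_per_L",
            "avg_bp_stem2", "MFE4", "MFE5")]),
        np.array([comp[f"freq2_{w}"] for w in kmer_names(2)]),
        np.array([comp[f"freq3_{w}"] for w in kmer_names(3)]),
        score_distance_dependent(seq, tables.distance_dependent),
    ]
    values = np.concatenate(parts)
    return FeatureVector(id=seq.id, values=values, warnings=thermo.warnings)


@dataclass
class FeatureMatrix:
    """Feature matrix for a batch, tagged with the manifest version."""

    ids: list
    X: np.ndarray
    manifest_version: str = MANIFEST_VERSION
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != N_FEATURES:
            raise ValueError(f"matrix must be (n, {N_FEATURES})")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("ids/rows mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        df.insert(0, "id", self.ids)
        with open(path, "w") as fh:
            fh.write(f"# manifest_version={self.manifest_version}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# manifest_version="):
                raise FormatError(f"{path}: missing manifest_version header")
            version = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t")
        if list(df.columns) != ["id"] + list(FEATURE_NAMES):
            raise FormatError(f"{path}: feature columns do not match the manifest")
        return cls(ids=df["id"].tolist(),
                   X=df[list(FEATURE_NAMES)].to_numpy(dtype=float),
                   manifest_version=version)


def featurize_many(
    items: list,
    tables: PotentialSet,
    stem_pct_reading: str = "literal",
) -> FeatureMatrix:
    """Featurize a list of (Sequence, SecondaryStructure) pairs."""
    vectors = [featurize(s, ss, tables, stem_pct_reading=stem_pct_reading)
               for s, ss in items]
    X = np.vstack([v.values for v in vectors]) if vectors else \
        np.empty((0, N_FEATURES))
    return FeatureMatrix(
        ids=[v.id for v in vectors], X=X,
        warnings=[v.warnings for v in vectors],
    )
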