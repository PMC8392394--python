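"""Construct pseudo pre-miRNA negatives from coding sequence.

Samples windows from synthetic CDS records at lengths matching a positive
set, folds them, and keeps only windows that resemble genuine precursors
(hairpin-forming, pairing- and energy-density matched).
"""

import numpy as np

from mirhairpin import (
    LengthSampler,
    PseudoFilter,
    extract_pseudo_hairpins,
    fold,
    fold_many,
    make_cds,
    make_hairpin,
)

rng = np.random.default_rng(5)
positives = [
    make_hairpin(int(rng.integers(18, 30)), int(rng.integers(4, 10)),
                 float(rng.uniform(0.1, 0.3)), seed=int(rng.integers(2 ** 31)))
    for _ in range(30)
]
pos_pairs = fold_many(positives, engine="auto")
sampler = LengthSampler.from_positives(positives)
filters = PseudoFilter.from_positives(pos_pairs)
print(f"similarity filters from {len(positives)} positives: "
      f"dP in [{filters.min_dp:.3f}, {filters.max_dp:.3f}], "
      f"dG in [{filters.min_dg:.3f}, {filters.max_dg:.3f}] per nt")

cds = [make_cds(200, seed=50 + i) for i in range(8)]
windows = extract_pseudo_hairpins(cds, 15, sampler, filters, seed=5)
print(f"accepted {len(windows)} pseudo hairpins, e.g.:")
for w in windows[:3]:
    ss = fold(w, engine="auto")
    print(f"  {w.id}: {len(w)} nt, {len(ss.pairs)} pairs, MFE {ss.mfe:.1f}")
print()
print("Window ids carry provenance (source record and 1-based coordinates);")
print("each accepted window folds into a hairpin whose pairing and energy")
print("density lie inside the positive set's observed range.")
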