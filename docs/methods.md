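# Methods

## Scope and model

`mirhairpin` classifies RNA stem-loop candidates as genuine plant pre-miRNA
precursors or pseudo hairpins. The model is a binary RBF-SVM over a fixed,
versioned 193-feature representation combining knowledge-based k-mer pair
pseudo-energies, secondary-structure element statistics and sequence
composition. The classifier assumes candidates are single pseudoknot-free
hairpin-scale sequences (tens to a few hundred nucleotides) over
{A, C, G, U}; sequences containing any other character are dropped on
input (with a logged count) rather than repaired, and T is silently read
as U so both RNA-coded and genome-derived FASTA work.

## Secondary structure

Every feature downstream of folding depends on one MFE structure per
sequence. The default engine is ViennaRNA (python bindings, falling back
to the `RNAfold` executable); its energies are kcal/mol. A self-contained
fallback — weighted Nussinov base-pair maximization with pair weights
GC = 3, AU = 2, GU = 1, minimum hairpin loop of 3 nt, and "mfe" defined as
the negated pairing score — keeps the entire pipeline runnable with no
external thermodynamics and is checkable against exhaustive enumeration at
small lengths. Among co-optimal fallback structures the sorted pair list
that is lexicographically smallest is returned, making the fallback
deterministic and oracle-comparable. Structures supplied in dot-bracket
files bypass folding entirely (`source="provided"`), so output from any
external folding tool can be featurized bit-for-bit. Coordinates are
1-based throughout the structure layer.

Structural elements are defined as: stem — maximal run of ≥ 3 stacked
pairs (a single unpaired position ends the run); loop — maximal unpaired
run enclosed by at least one pair (hairpin, interior and bulge loops all
count; external tails do not); bulge — maximal unpaired run of ≥ 3 nt
anywhere, terminal loop included (an option excludes it for the classical
reading); MCPN — the longest run of consecutive paired sequence positions.
The 10 sub-region unpaired ratios cut the primary sequence into contiguous
tenths, the first L mod 10 regions taking the extra position, which makes
the partition reproducible and order-independent.

## Knowledge-based potentials

The pseudo-energy of word pair x in bin b is
E(x, b) = −ln[(F⁺(x, b) + ε)/(F⁻(x, b) + ε)], with F± the relative
frequencies over the positive/negative training sets (each class
normalized by its total event count over the full word-pair × bin lattice)
and additive smoothing ε defaulting to 1/lattice-size, so unseen pairs are
exactly neutral and no entry is infinite. Word windows overlap; distances
and positions are relative to sequence length (half-open bins, last bin
closed), so potentials transfer across the precursor length range.

Three schemes feed the feature vector: (1) position-specific contact
potentials — for each base pair (i, j), the 2-mer starting at i paired
with the 2-mer ending at j, binned by i/L into 34 bins and scored as
per-bin mean energies (empty bins score 0); (2) distance-specific
potentials over all ordered k-mer start pairs i < j for k = 1..5, one
aggregate bin, scored as the mean energy (mean, not sum, so the feature is
length-comparable); (3) distance-dependent potentials for k = 1..3 with 20
relative-distance bins, scored as 20 bin means pooled over k at the event
level plus a per-k overall mean and the per-k population standard
deviation of the occupied bin means. The 34- and 26-dimensional
parameterizations preserve the dimensionalities and parameters (k ranges,
20 bins) of the published feature set they reconstruct; the binning of the
contact scheme is this package's own concrete choice. Trained tables carry
a fingerprint of their training inputs and travel inside the model bundle:
prediction never re-estimates them.

## Features, normalization, classifier

The 193 features are assembled in a fixed block order
(34 + 5 + 10 + 4 + 16 + 5 + 3 + 3 + 7 + 80 + 26), with names and order
frozen in a versioned manifest; models refuse matrices from a different
manifest version. Any ratio with a zero denominator (no stems, loops,
bulges or pairs; zero GC) is emitted as 0 and flagged per-sequence, so
unfoldable candidates score rather than crash. Two printed-definition
ambiguities are resolved explicitly: the three "%(X−Y)/n_stems" features
default to the literal double-division reading (|X−Y|·100/n_stems²) with a
switch for the per-pair reading, and the two per-stem averages are
disambiguated as pairs/stem (tot_bases/n_stems) versus paired
nucleotides/stem (pb/n_stems).

Training z-scores each column with training statistics (constant columns
map to 0; σ is stored, never refit at prediction). The SVM kernel is
K(Xᵢ, Xⱼ) = exp(−γ|Xᵢ − Xⱼ|²); the default γ = 1/(n·σ²) reads the
"generalized variance" σ² as the mean per-feature variance of the scaled
matrix (the determinant-of-covariance reading would make γ vanish for 193
features). Grid search selects (C, γ) by mean stratified-CV AUC — grids
default to C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and γ ∈ {default} ∪ {2⁻¹⁵, …, 2³} — with
ties broken toward smaller C, then smaller γ, and the full grid record kept
in the bundle. Prediction scores are a fixed logistic map of the SVM
margin: monotone, so the 0.5-score label equals the margin's sign, ranking
metrics are unaffected by the mapping, and repeated runs are byte-identical
under a seed. (A calibration fitted on held-out folds was considered and
rejected: it buys probability interpretability at the cost of guaranteed
order-consistency with the decision function.)

## Negatives from CDS

Pseudo hairpins are windows of coding sequence sampled at lengths drawn
from the positive set's empirical length distribution, folded, and kept
only if they (a) contain ≥ 1 stem, (b) have pairing density dP = pairs/L
inside the positive set's observed [min, max], and (c) have energy density
dG = MFE/L inside the positive set's observed range (optional percentile
trimming tightens both). Windows never overlap a previously accepted
window of the same source record; ids carry source and 1-based
coordinates. The similarity criterion is a documented reconstruction of
the standard pseudo-hairpin constructions in this tool lineage; the
originally used CDS corpus and constants are not public.

## Evaluation

Ac, Se, Sp and MCC follow the standard confusion-matrix formulas, with
MCC = 0 whenever a denominator factor vanishes. AUC is the Mann–Whitney
probability with ties counted half (delegated to scikit-learn and verified
against an O(n²) pairwise oracle in the tests). Cross-validation is
stratified — the training sets in this problem are class-imbalanced, and
stratification preserves the ratio per fold — and refits potentials,
scaler and SVM inside every training fold. Top-N consistency reports the
exclusive Venn-region cardinalities of the top-N id sets of 2–3 rankings,
with ties at rank N broken by id.

## Synthetic data

The generator emulates the two training classes: stem-loops (uniform
random 5' arm, loop, reverse-complement 3' arm with per-position point
mutations) and coding sequence (AUG start, sense codons from a fixed
stylized usage table with a mild 3rd-position A/U preference, one terminal
stop). Benchmarks draw stem lengths of 18–32 pairs and loops of 4–12 nt
(total 40–77 nt — compact relative to real plant precursors, chosen so
thousands of folds run in seconds), and both classes share one length
sampler so length is never the signal. A single `difficulty` knob in
[0, 1] scales the positive mutation rate linearly (0.02 + 0.28·d) and
replaces positives with CDS windows with probability d², giving a clean
benchmark at low difficulty, a monotone decay in separability, and an
identically-distributed (AUC ½) null at d = 1. The generator omits much of
what makes real data hard — multi-branched precursors, GU-rich wobbly
stems, genomic base composition, cross-species heterogeneity, near-duplicate
miRBase entries — so passing benchmarks demonstrate that the pipeline
recovers planted structure/composition signal, not that real-data accuracy
matches any published figure.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use 200+200 benchmarks for
held-out evaluation, 10- and 4-fold CV on 100+100, a label-permuted null
on the full 200+200 benchmark, 200 random sequences of length ≤ 14 for the
fold-vs-enumeration check, and toy sets for the potential-table oracle;
these sizes are the package's own choice of a desk-scale experiment.
Tolerances: exact equality where arithmetic is exact (fold scores, region
conservation), 1e-9/1e-10 for float aggregation identities, and interval
assertions for stochastic quantities. Seeds flow from a single integer;
everything from sequence generation to fold assignment and SVM internals
is derived from it.

## Known limitations

Real miRBase/CDS corpora are not bundled, so published benchmark figures
on those corpora are out of scope here; the fallback folder is a pairing
heuristic, not a thermodynamic model, and should not be used for energy
interpretation; pseudoknots, multi-loop typing and suboptimal ensembles
are unsupported; and the position-specific/distance-dependent feature
parameterizations are reconstructions that preserve published
dimensionalities rather than replications of unpublished code.
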