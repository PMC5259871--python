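# Methods

## Model and assumptions

The method treats the epigenome of one cell type as K binned signal
tracks and asks where subsets of marks share local signal *shape*. The
unit of evidence is the Pearson correlation of two marks' bin profiles
within one fixed-width region; a mark set M is coherent in a region iff
*every* pair of M is correlated at or above the threshold there
(per-region clique semantics). This is deliberately stronger than
connectivity in the co-occurrence graph: requiring all pairs is what
makes "co-occupied by a modification set" meaningful, and it makes
support anti-monotone under mark-set growth, which both the DFS pruning
and the brute-force oracles rely on.

Cell types are treated as an unordered set: a spatio-temporal cluster
records in *which* stages a signature is conserved, not a trajectory
order. No significance testing against a null is attempted; the miners
are exact enumerators, and the false-positive behaviour is characterized
empirically on background-only simulations instead.

## Geometry and conventions

- Bins: 200 bp, non-overlapping. Regions: 5 kb = B = 25 bins. Both
  configurable; region size must be an exact multiple of bin size.
- Coordinates are 0-based half-open (BED convention) throughout.
- Trailing chromosome stubs shorter than one region are dropped rather
  than padded, so every region matrix has exactly B columns and every
  correlation is over vectors of equal length. Region indices are global,
  contiguous and fixed by chromosome file order — not lexicographic — so
  all outputs are deterministic functions of the inputs.

## Transformation

Tags are assigned to the bin containing their midpoint by default,
unstranded, with no fragment extension: the simplest deterministic rule,
and strand is irrelevant to binned co-occurrence. A strand-aware
5'-end-with-shift mode (`mode="five_prime"`, `shift` in bp) is available
for workflows that prefer the cut-site convention; the midpoint rule is
what the defaults and the end-to-end tests use. Counts are divided by the total
number of *counted* (in-scope) tags — a proportion p ∈ [0, 1], which the
arcsine transform arcsin(√p) requires; per-million scaling would violate
it. arcsin(√p) is the standard variance-stabilizing transform for
proportions; an `asinh` alternative is available via the `transform`
switch for sensitivity analysis. A zero-tag library yields an all-zero
track rather than an error. Pearson is invariant to the affine part of
any monotone rescaling only approximately, so the transform choice can
matter near the threshold; both options are exposed for that reason.

Pre-binned bedGraph input bypasses tag counting: each record's value is
allocated to overlapping bins proportionally to overlap length and the
global value sum plays the role of the library size.

## Correlation and the graph

Pearson correlation (Spearman configurable) over the B paired bin values;
the threshold comparison is inclusive (≥ 0.9 by default). Zero-variance
rows produce an undefined (NaN) coefficient and are defined as *not*
coherent with anything — a flat profile carries no co-variation evidence.
This NaN-fails-the-threshold rule is mirrored exactly in the brute-force
oracles and the verifier. Correlations are computed vectorized over all
regions at once (einsum over the centered tensor), clipped to [-1, 1]
against floating-point drift.

## Mining

Spatial: depth-first search over mark sets in canonical (input) order,
extending only with later-ordered marks so every set is visited once.
The running support travels down the recursion as a Python int bitmask
(region r ↔ bit r); a branch is pruned as soon as its support drops below
the minimum region count, which is sound because support is
anti-monotone. A set is emitted iff it meets both size thresholds and is
*closed*: no mark outside it preserves the support. Closed (rather than
strictly maximal) semantics are used because the method's natural output
contains subset patterns with strictly larger support alongside their
supersets, which maximality would suppress; closedness is the standard
non-redundant pattern semantics consistent with that. Ranking by region
count can therefore place a subset pattern above its superset — the
subset's support is a superset of the superset's — and the ranking rule
here is strictly |S| descending with lexicographic tie-break.

Spatio-temporal: cell-type subsets are enumerated explicitly (≤ 2⁵ = 32
at the five-cell-type scale the method targets) rather than grown
incrementally; at this size exhaustive enumeration is simpler and
obviously correct. For each subset T the per-cell-type graphs are
intersected edge-wise and closed spatial mining runs on the intersection;
a resulting (M, S) is kept iff T is maximal for it — no outside cell type
t has S ⊆ support_t(M), which is exactly the condition under which
T ∪ {t} would reproduce the same (M, S). Maximal T is unique for a given
(M, S), so this yields each conserved pattern once. The same mark/region
thresholds govern both mining stages by default, and the minimum
cell-type count defaults to 2 (a one-cell-type triple is just a spatial
cluster).

Defaults: θ = 0.9, min_marks = 5, min_region_fraction = 0.1% (count =
⌈fraction · N⌉, never below 1), min_cell_types = 2.

## Oracles and verification

Three independent routes guard the miners: (i) `brute_force_spatial` /
`brute_force_st` enumerate all 2^K mark subsets (and cell-type subsets)
directly from the definitions with frozensets, sharing no code with the
bitmask DFS, guarded to K ≤ 16 and T ≤ 8; (ii) a per-region clique oracle
in the test suite recomputes support a third way; (iii) `verify_cluster`
bypasses the graph entirely and recomputes all pairwise correlations from
the raw region tensor, distinguishing *validity* (all pairs pass in all
member regions) from *completeness* (S is the full support).

## Synthetic data

The generator emulates the target data shape — T cell types × K marks ×
a binned genome — with planted (M, S, T) blocks. Coherence is induced the
way the model assumes it arises: one latent smooth unimodal bump (random
center in the middle half of the region, width 1.5–4 bins) is drawn per
(block, cell type, region) and shared by all the block's marks, scaled by
a per-mark log-normal factor (σ = 0.25) and perturbed by Gaussian noise
σ_in. Latent signal maps to expected tag counts through `reads_per_unit`
and integer tags are drawn Poisson per bin, emitted as unit intervals at
bin midpoints — so the preprocessing stage is exercised on realistic
integer counts, not on the latent signal. Blocks must be disjoint in
(mark, region, cell type) cells.

Randomness is structured as one stream per (cell type, mark) for noise
and tag sampling, plus per-block streams for profiles and scale factors,
all keyed off the master seed: adding a mark never perturbs other tracks,
and a fixed seed reproduces every file byte-identically.

Default study conditions (`default_sim_params`): one 300 kb chromosome
(N = 60 regions, B = 25), the 16-mark Roadmap hESC panel, 4 cell types,
three disjoint blocks of 6 marks × 12 regions spanning 4, 2 and 3 cell
types, amplitude 5.0, σ_in = 0.05, background rate 0.1 with sd 0.05, and
50 expected tags per unit latent signal. These sizes keep a full
multi-seed pipeline run in seconds while leaving the planted correlation
(≈ 0.99 after Poisson noise and the arcsine transform) clearly above the
0.9 threshold and chance background correlations (r over 25 bins of
independent noise) far below it. What passing tests on this generator
shows is that the pipeline recovers block-structured, profile-shared
coherence from Poisson tag noise; what it does not show is robustness to
features of real ChIP-seq the generator omits — fragment-length effects,
GC and mappability bias, input/control structure, replicate variation,
or marks whose co-variation is only partial within a region.

## Numerical and degenerate-input choices

- NaN (undefined) correlations never satisfy the threshold; comparisons
  are inclusive (≥).
- Correlations are clipped to [-1, 1]; exactly collinear integer profiles
  reproduce ±1 to machine precision (checked in the tests).
- Ties in all output orderings break lexicographically on sorted mark
  labels; spatio-temporal output sorts by |T| desc, |S| desc, marks.
- Tracks persisted as bin-resolution bedGraph use `%.17g` floats and
  round-trip bit-exactly; graphs and cluster lists serialize to JSON with
  sorted keys, so re-running any stage with unchanged inputs reproduces
  artifacts byte-identically.
- Tags on chromosomes absent from the layout are skipped with a warning
  (not an error); tags with midpoint in a dropped partial region are
  skipped silently. Neither enters the library size.

## Problem sizes used in the automated checks

Oracle-equivalence checks run on random graphs with K ≤ 8 marks and
N ≤ 200 regions (spatial) and K ≤ 6, N ≤ 100, 3 cell types
(spatio-temporal), 20 instances each; recovery and false-positive checks
run the full pipeline on the default study conditions over 10 and 20
seeds respectively. These sizes were chosen so each property is checked
across many independent instances in seconds.

## Known limitations

- Exhaustive closed-pattern enumeration is exponential in K in the worst
  case; it is practical for histone-mark panels (K ≈ 16) but not for
  hundreds of tracks.
- Region sets as int bitmasks scale to genome-wide N (millions of bits)
  but with a memory cost per DFS node; a sparse-set backend would suit
  very large N with sparse edges better.
- No control-track subtraction, duplicate removal or mappability
  correction; inputs are assumed pre-filtered to the user's standards.
- The temporal dimension is set-valued; lineage-tree-constrained subsets
  and trajectory ordering are out of scope.
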