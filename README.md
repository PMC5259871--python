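# stcluster

Mining of **spatial** and **spatio-temporal clusters** of epigenetic
modifications from binned ChIP-seq signal across multiple cell types.

During embryonic stem cell differentiation, histone modifications act
combinatorially: groups of marks (H3K4me2, H3K27ac, H3K9ac, ...) rise and
fall together over the same regulatory regions, and some of these
combinatorial signatures are conserved across developmental stages while
others are stage-specific. `stcluster` is for computational epigenomics
work that asks *which* mark combinations co-vary, *where* in the genome,
and *in which subsets of cell types* — given per-cell-type, per-mark tag
maps (BED) or pre-binned coverage (bedGraph).

## Method

1. **Data transformation.** The genome is tiled with non-overlapping
   200 bp bins and cut into 5 kb regions of B = 25 bins. Tags are counted
   per bin (midpoint rule), normalized by library size and
   variance-stabilized with the arcsine transform arcsin(√p). Each cell
   type's signal becomes N region matrices *R*ᵢ of shape K marks × B bins.
2. **Co-occurrence graph.** In every region, the Pearson correlation of
   each mark pair's bin profiles is computed. The co-occurrence graph
   G = (V, E) has the K marks as vertices; an edge (hᵢ, hⱼ) carries the
   set of regions where corr ≥ θ (default θ = 0.9).
3. **Spatial clusters.** A spatial cluster is a bicluster (M, S): every
   pair of marks in M is coherent in every region of S, S is the full
   support of M (the intersection of the pairwise edge region sets), and
   M is *closed* — no mark can join without shrinking S. A depth-first
   search over mark sets with support-based pruning enumerates every
   closed cluster with |M| ≥ 5 marks and |S| ≥ 0.1% of the N regions
   (defaults; both configurable).
4. **Spatio-temporal clusters.** Triples (M, S, T) extend the biclusters
   across cell-type subsets T: the per-cell-type graphs of T are
   intersected edge-wise, closed spatial mining runs on the intersection,
   and only triples with maximal T are kept — conserved epigenetic
   signatures of the differentiation process.

Brute-force enumeration oracles (`brute_force_spatial`, `brute_force_st`),
a raw-signal re-verifier (`verify_cluster`), and a synthetic generator
with planted ground-truth blocks make every stage checkable end to end.

## Worked example

Simulate a 4-cell-type, 16-mark dataset on a 300 kb toy genome (N = 60
regions) with three planted coherent blocks, then run the full chain:

```sh
stcluster simulate --out demo/data --seed 42
stcluster bin --manifest demo/data/manifest.tsv \
              --chrom-sizes demo/data/chrom.sizes --out demo/run
stcluster graph --out demo/run
stcluster mine-spatial --out demo/run
stcluster mine-st --out demo/run
stcluster summarize --out demo/run
stcluster verify --out demo/run
```

which prints:

```
simulated 64 tracks, 1952802 tags -> demo/data
binned 64 tracks over 60 regions -> demo/run
built 4 graphs (threshold 0.9) -> demo/run
mined 9 spatial clusters (threshold 0.9, min_marks 5, min fraction 0.10%)
mined 3 spatio-temporal clusters -> demo/run
wrote occurrence_frequencies.tsv and top_clusters.tsv -> demo/run
verified 12 clusters, 0 failures
```

The 9 spatial clusters are the planted blocks seen from each member cell
type; the 3 spatio-temporal clusters are the blocks with their maximal
cell-type sets. `demo/run/st_clusters.tsv` begins:

```
marks	cell_types	n_regions	regions
H2AK5ac;H2BK120ac;H2BK5ac;H3K18ac;H3K23ac;H3K27ac	H1;MesenchymalStem;Mesendoderm;Trophoblast	12	5,6,...,16
H3K4me2;H3K4me3;H3K79me1;H3K9ac;H3K9me3;H4K8ac	MesenchymalStem;Mesendoderm;Trophoblast	12	35,36,...,46
H3K27ac;H3K27me3;H3K36me3;H3K4ac;H3K4me1;H3K4me2	H1;Mesendoderm	12	20,21,...,31
```

i.e. each planted (marks × regions × cell types) block is recovered
exactly: a 6-mark signature conserved in all four cell types over regions
5–16, one shared by three of the four over regions 35–46, and one private
to H1 + Mesendoderm over regions 20–31. `verify` re-checks every emitted
cluster against the raw binned signal (all pairwise correlations ≥ 0.9 in
all member regions and cell types) and exits non-zero on any failure.

The same analysis is available as a library:

```python
import stcluster as sc

res = sc.simulate_dataset(sc.default_sim_params(), seed=42)
tensors, graphs, spatial, st = sc.run_pipeline(res)
print(sc.recovery_score(res.truth, st))
# [(1.0, 1.0, 1.0), (1.0, 1.0, 1.0), (1.0, 1.0, 1.0)]
```

where each triple is the (marks, regions, cell-types) Jaccard overlap of
a planted block with its best-matching mined cluster.

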