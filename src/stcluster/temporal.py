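"""Spatio-temporal cluster mining across cell types.

A spatio-temporal cluster is a tricluster (M, S, T): in every cell type of
T, every pair of marks in M is coherent in every region of S. It captures
an epigenetic signature conserved across a subset of the differentiation
stages. Mining enumerates cell-type subsets explicitly (the temporal
dimension is tiny — 5 cell types give at most 32 subsets), intersects the
per-cell-type co-occurrence graphs edge-wise, runs closed spatial mining
on the intersection, and keeps only triples that are closed in T: no
additional cell type supports the same (M, S).

Closedness in all three dimensions makes the output non-redundant: a
pattern conserved in 4 of 5 cell types is reported once, with its maximal
cell-type set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple

from .cograph import CooccurrenceGraph
from .preprocess import RegionTensor
from .spatial import (
    MiningParams,
    SpatialCluster,
    VerificationReport,
    mine_spatial_clusters,
    support,
    verify_cluster,
)

__all__ = [
    "SpatioTemporalCluster",
    "intersect_graphs",
    "mine_st_clusters",
    "brute_force_st",
    "verify_st_cluster",
]

BRUTE_FORCE_MAX_T = 8
BRUTE_FORCE_MAX_K = 16


@dataclass(frozen=True)
class SpatioTemporalCluster:
    """(mark set M, region set S, cell-type set T) tricluster."""

    marks: FrozenSet[str]
    regions: FrozenSet[int]
    cell_types: FrozenSet[str]

    @property
    def sorted_marks(self) -> Tuple[str, ...]:
        return tuple(sorted(self.marks))

    @property
    def sorted_regions(self) -> Tuple[int, ...]:
        return tuple(sorted(self.regions))

    @property
    def sorted_cell_types(self) -> Tuple[str, ...]:
        return tuple(sorted(self.cell_types))

    def key(self) -> tuple:
        """Output order: |T| desc, |S| desc, lexicographic marks."""
        return (-len(self.cell_types), -len(self.regions), self.sorted_marks)

    def to_json_dict(self) -> dict:
        return {
            "marks": list(self.sorted_marks),
            "cell_types": list(self.sorted_cell_types),
            "n_regions": len(self.regions),
            "regions": list(self.sorted_regions),
        }


def _check_consistent(graphs: Sequence[CooccurrenceGraph]) -> None:
    if len(graphs) < 2:
        raise ValueError("need at least 2 cell-type graphs")
    ref = graphs[0]
    for g in graphs[1:]:
        if g.marks != ref.marks:
            raise ValueError("graphs have different mark sets/orders")
        if g.n_regions != ref.n_regions:
            raise ValueError("graphs have different region counts")
        if g.threshold != ref.threshold:
            raise ValueError("graphs built at different thresholds")
    names = [g.cell_type for g in graphs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cell-type labels")


def intersect_graphs(graphs: Sequence[CooccurrenceGraph]) -> CooccurrenceGraph:
    """Edge-wise intersection: a pair is coherent for a cell-type set in
    exactly the regions where it is coherent in every member."""
    if len(graphs) >= 2:
        _check_consistent(graphs)
    ref = graphs[0]
    keys = set(graphs[0].edges)
    for g in graphs[1:]:
        keys &= set(g.edges)
    edges = {}
    for key in keys:
        s = frozenset.intersection(*(g.edges[key] for g in graphs))
        if s:
            edges[key] = s
    return CooccurrenceGraph(
        cell_type="+".join(g.cell_type for g in graphs),
        marks=ref.marks,
        n_regions=ref.n_regions,
        threshold=ref.threshold,
        edges=edges,
    )


def mine_st_clusters(
    graphs: Sequence[CooccurrenceGraph], params: MiningParams
) -> List[SpatioTemporalCluster]:
    """Mine all closed spatio-temporal clusters from per-cell-type graphs.

    For each cell-type subset T with ``|T| >= min_cell_types``, closed
    spatial mining runs on the intersected graph of T; the resulting
    (M, S) pairs are kept only when T is maximal for them — no outside
    cell type t has ``S`` inside ``support_t(M)``, which is exactly the
    condition under which T could grow without changing (M, S).
    """
    _check_consistent(graphs)
    n_t = len(graphs)
    results: List[SpatioTemporalCluster] = []
    for size in range(max(1, params.min_cell_types), n_t + 1):
        for t_idx in combinations(range(n_t), size):
            sub = [graphs[t] for t in t_idx]
            g_int = intersect_graphs(sub) if len(sub) > 1 else sub[0]
            for cl in mine_spatial_clusters(g_int, params):
                t_closed = True
                for t in range(n_t):
                    if t in t_idx:
                        continue
                    if cl.regions <= support(graphs[t], cl.marks):
                        t_closed = False
                        break
                if t_closed:
                    results.append(
                        SpatioTemporalCluster(
                            marks=cl.marks,
                            regions=cl.regions,
                            cell_types=frozenset(graphs[t].cell_type for t in t_idx),
                        )
                    )
    results.sort(key=SpatioTemporalCluster.key)
    return results


def brute_force_st(
    graphs: Sequence[CooccurrenceGraph], params: MiningParams
) -> List[SpatioTemporalCluster]:
    """Exhaustive (M, T) oracle for :func:`mine_st_clusters`.

    Enumerates every mark subset and every cell-type subset, computes the
    joint support directly from edge sets, and filters to triples closed
    in M and in T per the definitions. Guarded to K <= 16 and T <= 8.
    """
    _check_consistent(graphs)
    K = len(graphs[0].marks)
    n_t = len(graphs)
    if K > BRUTE_FORCE_MAX_K or n_t > BRUTE_FORCE_MAX_T:
        raise ValueError(f"brute force refused: K={K}, T={n_t}")
    marks = graphs[0].marks
    min_count = params.min_region_count(graphs[0].n_regions)

    def joint_support(midx: Tuple[int, ...], t_idx: Tuple[int, ...]) -> FrozenSet[int]:
        out: set | None = None
        for t in t_idx:
            cur: set | None = None
            for a, b in combinations(midx, 2):
                es = graphs[t].edges.get((a, b))
                if es is None:
                    return frozenset()
                cur = set(es) if cur is None else cur & es
            out = cur if out is None else out & cur
            if not out:
                return frozenset()
        return frozenset(out)

    results = []
    for msize in range(params.min_marks, K + 1):
        for midx in combinations(range(K), msize):
            for tsize in range(max(1, params.min_cell_types), n_t + 1):
                for t_idx in combinations(range(n_t), tsize):
                    S = joint_support(midx, t_idx)
                    if len(S) < min_count:
                        continue
                    # closed in M
                    m_closed = True
                    for h in range(K):
                        if h in midx:
                            continue
                        if joint_support(tuple(sorted(midx + (h,))), t_idx) == S:
                            m_closed = False
                            break
                    if not m_closed:
                        continue
                    # closed in T
                    t_closed = True
                    for t in range(n_t):
                        if t in t_idx:
                            continue
                        if S <= joint_support(midx, (t,)):
                            t_closed = False
                            break
                    if not t_closed:
                        continue
                    results.append(
                        SpatioTemporalCluster(
                            marks=frozenset(marks[m] for m in midx),
                            regions=S,
                            cell_types=frozenset(graphs[t].cell_type for t in t_idx),
                        )
                    )
    results.sort(key=SpatioTemporalCluster.key)
    return results


def verify_st_cluster(
    tensors: Mapping[str, RegionTensor],
    cluster: SpatioTemporalCluster,
    params: MiningParams,
) -> Dict[str, VerificationReport]:
    """Re-check a tricluster against the raw tensors of every member cell type.

    Restricting the triple to each t in T must give a valid (not
    necessarily closed) spatial pattern there.
    """
    reports = {}
    for ct in cluster.sorted_cell_types:
        if ct not in tensors:
            raise KeyError(f"no tensor for cell type {ct!r}")
        sp = SpatialCluster(cell_type=ct, marks=cluster.marks, regions=cluster.regions)
        reports[ct] = verify_cluster(tensors[ct], sp, params)
    return reports
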