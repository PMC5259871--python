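"""Closed spatial-cluster mining on the co-occurrence graph.

A spatial cluster is a bicluster (mark set M, region set S) within one
cell type: every pair of marks in M is coherent in every region of S, S is
the *full* support of M (the intersection of the pairwise edge region
sets), and M is *closed* — no further mark can be added without shrinking
S. Closed patterns are the canonical non-redundant enumeration unit: every
coherent mark set is represented by the closed set with the same support.

The miner runs a depth-first search over mark sets in canonical (input)
order, carrying the running support down the recursion and pruning any
branch whose support drops below the minimum region count (support is
anti-monotone under mark-set growth). A brute-force enumerator over all
2^K mark subsets serves as an independent oracle at small K, and
``verify_cluster`` re-checks any cluster against the raw region tensor,
bypassing the graph entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

import numpy as np

from .cograph import CooccurrenceGraph, all_correlations
from .preprocess import RegionTensor

__all__ = [
    "MiningParams",
    "SpatialCluster",
    "support",
    "mine_spatial_clusters",
    "brute_force_spatial",
    "verify_cluster",
    "VerificationReport",
]

BRUTE_FORCE_MAX_K = 16


@dataclass(frozen=True)
class MiningParams:
    """Thresholds governing cluster mining.

    min_marks
        Minimum modifications per cluster (default 5).
    min_region_fraction
        Minimum support as a fraction of the N regions (default 0.001,
        i.e. 0.1% of the genome); the count is the ceiling of
        ``fraction * N`` and never below 1.
    threshold
        Correlation threshold inherited by verification (default 0.9).
    min_cell_types
        Minimum cell types per spatio-temporal cluster (default 2).
    """

    min_marks: int = 5
    min_region_fraction: float = 0.001
    threshold: float = 0.9
    min_cell_types: int = 2

    def __post_init__(self) -> None:
        if self.min_marks < 2:
            raise ValueError("min_marks must be >= 2")
        if not 0 < self.min_region_fraction <= 1:
            raise ValueError("min_region_fraction must be in (0, 1]")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.min_cell_types < 1:
            raise ValueError("min_cell_types must be >= 1")

    def min_region_count(self, n_regions: int) -> int:
        return max(1, math.ceil(self.min_region_fraction * n_regions))


@dataclass(frozen=True, order=True)
class SpatialCluster:
    """(cell type, mark set M, region set S) bicluster."""

    cell_type: str
    marks: FrozenSet[str] = field(compare=False)
    regions: FrozenSet[int] = field(compare=False)

    @property
    def sorted_marks(self) -> Tuple[str, ...]:
        return tuple(sorted(self.marks))

    @property
    def sorted_regions(self) -> Tuple[int, ...]:
        return tuple(sorted(self.regions))

    def key(self) -> tuple:
        """Deterministic output ordering: |S| descending, marks lexicographic."""
        return (-len(self.regions), self.sorted_marks)

    def to_json_dict(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "marks": list(self.sorted_marks),
            "n_regions": len(self.regions),
            "regions": list(self.sorted_regions),
        }


def support(graph: CooccurrenceGraph, marks: Iterable[str]) -> FrozenSet[int]:
    """Full support of a mark set: regions where every pair is coherent.

    Equals the intersection over all unordered pairs of M of the pair's
    edge region set; a missing edge makes the support empty.
    """
    M = sorted({graph.mark_index(m) for m in marks})
    if len(M) < 2:
        raise ValueError("support needs at least 2 distinct marks")
    out: FrozenSet[int] | None = None
    for a in range(len(M)):
        for b in range(a + 1, len(M)):
            es = graph.edges.get((M[a], M[b]))
            if es is None:
                return frozenset()
            out = es if out is None else out & es
            if not out:
                return frozenset()
    return frozenset(out)


# --------------------------------------------------------------------- miner


def _edge_masks(graph: CooccurrenceGraph) -> Dict[Tuple[int, int], int]:
    """Edge region sets as int bitmasks (bit r set <=> region r present)."""
    masks = {}
    for key, s in graph.edges.items():
        m = 0
        for r in s:
            m |= 1 << r
        masks[key] = m
    return masks


def _mask_to_set(mask: int) -> FrozenSet[int]:
    out = []
    r = 0
    while mask:
        if mask & 1:
            out.append(r)
        mask >>= 1
        r += 1
    return frozenset(out)


def mine_spatial_clusters(
    graph: CooccurrenceGraph, params: MiningParams
) -> List[SpatialCluster]:
    """Enumerate all closed spatial clusters meeting the size thresholds.

    DFS over mark sets in ``graph.marks`` order, extending only with
    later-ordered marks so each set is visited once; the running support
    (a bitmask intersection) is carried down and branches falling below
    the minimum region count are pruned. Emitted sets are exactly those
    with ``|M| >= min_marks``, ``|support(M)| >= min_region_count`` and no
    extension mark preserving the support. Output is sorted by
    (|S| descending, lexicographic mark list).
    """
    K = len(graph.marks)
    min_count = params.min_region_count(graph.n_regions)
    masks = _edge_masks(graph)
    results: List[SpatialCluster] = []

    def extend_support(members: List[int], sup: int, h: int) -> int:
        """Support of members + {h}: intersect sup with every (m, h) edge."""
        for m in members:
            e = masks.get((m, h) if m < h else (h, m))
            if e is None:
                return 0
            sup &= e
            if sup == 0:
                return 0
        return sup

    def is_closed(members: List[int], sup: int) -> bool:
        member_set = set(members)
        for h in range(K):
            if h in member_set:
                continue
            if extend_support(members, sup, h) == sup:
                return False
        return True

    def dfs(members: List[int], sup: int, start: int) -> None:
        if len(members) >= params.min_marks and is_closed(members, sup):
            results.append(
                SpatialCluster(
                    cell_type=graph.cell_type,
                    marks=frozenset(graph.marks[m] for m in members),
                    regions=_mask_to_set(sup),
                )
            )
        for h in range(start, K):
            sup2 = extend_support(members, sup, h)
            if sup2.bit_count() >= min_count:
                members.append(h)
                dfs(members, sup2, h + 1)
                members.pop()

    for i in range(K):
        for j in range(i + 1, K):
            e = masks.get((i, j))
            if e is not None and e.bit_count() >= min_count:
                dfs([i, j], e, j + 1)

    results.sort(key=SpatialCluster.key)
    return results


# -------------------------------------------------------------------- oracle


def brute_force_spatial(
    graph: CooccurrenceGraph, params: MiningParams
) -> List[SpatialCluster]:
    """Exhaustive-subset oracle for :func:`mine_spatial_clusters`.

    Enumerates every mark subset of size >= min_marks directly from the
    definitions (pairwise edge-set intersection, then the closedness
    filter), with no shared state with the DFS miner. Guarded to K <= 16.
    """
    from itertools import combinations

    K = len(graph.marks)
    if K > BRUTE_FORCE_MAX_K:
        raise ValueError(f"brute force refused: K={K} > {BRUTE_FORCE_MAX_K}")
    min_count = params.min_region_count(graph.n_regions)

    def subset_support(idx: Tuple[int, ...]) -> FrozenSet[int]:
        sets = []
        for a, b in combinations(idx, 2):
            es = graph.edges.get((a, b))
            if es is None:
                return frozenset()
            sets.append(es)
        return frozenset(set.intersection(*map(set, sets)))

    out = []
    for size in range(params.min_marks, K + 1):
        for idx in combinations(range(K), size):
            sup = subset_support(idx)
            if len(sup) < min_count:
                continue
            closed = True
            for h in range(K):
                if h in idx:
                    continue
                if subset_support(tuple(sorted(idx + (h,)))) == sup:
                    closed = False
                    break
            if closed:
                out.append(
                    SpatialCluster(
                        cell_type=graph.cell_type,
                        marks=frozenset(graph.marks[m] for m in idx),
                        regions=sup,
                    )
                )
    out.sort(key=SpatialCluster.key)
    return out


# -------------------------------------------------------------- verification


@dataclass(frozen=True)
class VerificationReport:
    """Re-check of a cluster against the raw signal tensor.

    ``passed`` requires every pairwise correlation in every member region
    to be defined and >= threshold, and the size thresholds to hold.
    ``is_full_support`` additionally flags whether S misses any supported
    region (completeness; a subset S still passes the pairwise checks).
    """

    passed: bool
    pairwise_ok: bool
    sizes_ok: bool
    is_full_support: bool
    failures: Tuple[Tuple[int, Tuple[str, str], float], ...]  # (region, pair, value)
    missing_regions: FrozenSet[int]  # supported but absent from S


def verify_cluster(
    tensor: RegionTensor, cluster: SpatialCluster, params: MiningParams
) -> VerificationReport:
    """Validate a spatial cluster directly from the region matrices.

    Recomputes all pairwise correlations of the cluster's marks in every
    member region (bypassing the graph) and checks them against
    ``params.threshold``; also recomputes the full support to flag
    completeness.
    """
    midx = sorted(tensor.marks.index(m) for m in cluster.marks)
    for m in cluster.marks:
        if m not in tensor.marks:
            raise KeyError(f"unknown mark {m!r}")
    for r in cluster.regions:
        if not 0 <= r < tensor.n_regions:
            raise KeyError(f"region {r} not in tensor")

    corr = all_correlations(tensor)  # (N, K, K)
    failures = []
    for r in sorted(cluster.regions):
        for a in range(len(midx)):
            for b in range(a + 1, len(midx)):
                v = corr[r, midx[a], midx[b]]
                if not (v >= params.threshold):  # NaN fails too
                    failures.append(
                        (
                            r,
                            (tensor.marks[midx[a]], tensor.marks[midx[b]]),
                            float(v),
                        )
                    )
    pairwise_ok = not failures

    # full support from raw signal
    sub = corr[np.ix_(range(tensor.n_regions), midx, midx)]
    with np.errstate(invalid="ignore"):
        ok_all = np.ones(tensor.n_regions, dtype=bool)
        for a in range(len(midx)):
            for b in range(a + 1, len(midx)):
                ok_all &= sub[:, a, b] >= params.threshold
    full_support = frozenset(int(r) for r in np.flatnonzero(ok_all))
    missing = full_support - cluster.regions

    sizes_ok = (
        len(cluster.marks) >= params.min_marks
        and len(cluster.regions) >= params.min_region_count(tensor.n_regions)
    )
    return VerificationReport(
        passed=pairwise_ok and sizes_ok,
        pairwise_ok=pairwise_ok,
        sizes_ok=sizes_ok,
        is_full_support=not missing,
        failures=tuple(failures[:20]),
        missing_regions=missing,
    )
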