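"""Post-mining summaries: per-mark occurrence frequencies and top-k ranking.

The occurrence frequency of a modification is the fraction of the N
genomic regions covered by the union of the region sets of all spatial
clusters whose mark set contains it. Counting the union (not the multiset
sum) keeps the value a true ratio in [0, 1] even when clusters overlap.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

import pandas as pd

from .spatial import SpatialCluster

__all__ = ["occurrence_frequency", "rank_clusters"]


def occurrence_frequency(
    clusters: Iterable[SpatialCluster],
    n_regions: int,
    marks: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per (cell type, mark) occurrence frequency table.

    Rows are cell types (sorted), columns marks (given order, or the
    sorted union of marks seen); a mark appearing in no cluster of a cell
    type gets 0. Values are |union of S over containing clusters| / N.
    """
    clusters = list(clusters)
    for cl in clusters:
        if cl.regions and max(cl.regions) >= n_regions:
            raise ValueError("cluster region index >= n_regions")
    cell_types = sorted({cl.cell_type for cl in clusters})
    if marks is None:
        marks = sorted({m for cl in clusters for m in cl.marks})
    cover: dict = {(ct, m): set() for ct in cell_types for m in marks}
    for cl in clusters:
        for m in cl.marks:
            if (cl.cell_type, m) in cover:
                cover[(cl.cell_type, m)] |= cl.regions
    table = pd.DataFrame(
        [
            [len(cover[(ct, m)]) / n_regions if n_regions else 0.0 for m in marks]
            for ct in cell_types
        ],
        index=pd.Index(cell_types, name="cell_type"),
        columns=list(marks),
    )
    return table


def rank_clusters(
    clusters: Iterable[SpatialCluster], k: int = 10
) -> List[SpatialCluster]:
    """Top-k clusters by region count, ties broken by lexicographic marks.

    Returns fewer than k when fewer clusters exist; the result is a prefix
    of the full sorted list and stable across runs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return sorted(clusters, key=SpatialCluster.key)[:k]
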