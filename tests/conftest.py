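from __future__ import annotations

import numpy as np
import pytest

from stcluster import GenomeLayout, MiningParams
from stcluster.cograph import CooccurrenceGraph


@pytest.fixture
def small_layout() -> GenomeLayout:
    """Two chromosomes, 4 + 2 regions of 5 kb (bin 200, B = 25)."""
    return GenomeLayout((("chr1", 20_000), ("chr2", 10_000)))


def make_random_graph(
    rng: np.random.Generator,
    K: int,
    N: int,
    p_edge: float = 0.85,
    density: float = 0.5,
    cell_type: str = "c",
    threshold: float = 0.9,
) -> CooccurrenceGraph:
    """Random co-occurrence graph with random edge region sets."""
    edges = {}
    for i in range(K):
        for j in range(i + 1, K):
            if rng.random() < p_edge:
                s = frozenset(int(r) for r in np.flatnonzero(rng.random(N) < density))
                if s:
                    edges[(i, j)] = s
    marks = tuple(f"m{i:02d}" for i in range(K))
    return CooccurrenceGraph(
        cell_type=cell_type, marks=marks, n_regions=N, threshold=threshold, edges=edges
    )


def graph_from_edges(
    marks: tuple, edges_by_label: dict, n_regions: int, cell_type: str = "c"
) -> CooccurrenceGraph:
    """Build a graph from {(mark_a, mark_b): iterable of regions}."""
    idx = {m: i for i, m in enumerate(marks)}
    edges = {}
    for (a, b), regs in edges_by_label.items():
        i, j = sorted((idx[a], idx[b]))
        edges[(i, j)] = frozenset(regs)
    return CooccurrenceGraph(
        cell_type=cell_type, marks=marks, n_regions=n_regions, threshold=0.9, edges=edges
    )
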