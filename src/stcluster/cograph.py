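"""Per-region mark-mark correlation and the co-occurrence graph.

For every region i the K x B matrix R_i yields a K x K matrix of Pearson
coefficients between the bin profiles of each mark pair; a pair whose
coefficient reaches the threshold (default 0.9, inclusive) in region i is
*coherent* there. The co-occurrence graph G = (V, E) has the K marks as
vertices and an edge between two marks iff they are coherent in at least
one region; each edge carries the set of regions where that holds. The
graph is a compact index of all pairwise coherence and is the substrate
for cluster mining.

A zero-variance profile (e.g. an all-zero sparse mark) carries no
co-variation evidence: its correlations are *undefined* (NaN) and it is
never coherent with anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Tuple

import numpy as np
from scipy.stats import rankdata

from .preprocess import RegionTensor

__all__ = [
    "CooccurrenceGraph",
    "region_correlations",
    "all_correlations",
    "build_cooccurrence_graph",
]

DEFAULT_THRESHOLD = 0.9


@dataclass(frozen=True)
class CooccurrenceGraph:
    """Undirected mark graph with per-edge region support sets.

    ``edges`` is keyed by mark-index pairs ``(i, j)`` with ``i < j`` in
    ``marks`` order; values are frozensets of region indices. Edges with
    empty region sets are never stored.
    """

    cell_type: str
    marks: Tuple[str, ...]
    n_regions: int
    threshold: float
    edges: Dict[Tuple[int, int], FrozenSet[int]]

    def __post_init__(self) -> None:
        for (i, j), s in self.edges.items():
            if not (0 <= i < j < len(self.marks)):
                raise ValueError(f"bad edge key {(i, j)}")
            if not s:
                raise ValueError(f"edge {(i, j)} has empty region set")
            if s and (min(s) < 0 or max(s) >= self.n_regions):
                raise ValueError(f"edge {(i, j)} region out of [0, {self.n_regions})")

    def mark_index(self, mark: str) -> int:
        try:
            return self.marks.index(mark)
        except ValueError:
            raise KeyError(f"unknown mark {mark!r}") from None

    def edge_set(self, m1: str, m2: str) -> FrozenSet[int]:
        """Region set of the edge between two marks (empty if no edge)."""
        i, j = sorted((self.mark_index(m1), self.mark_index(m2)))
        if i == j:
            raise ValueError("self-loop query")
        return self.edges.get((i, j), frozenset())

    # ------------------------------------------------------------- serialization

    def to_json_dict(self) -> dict:
        edge_list = []
        for (i, j), s in self.edges.items():
            pair = sorted((self.marks[i], self.marks[j]))
            edge_list.append({"pair": pair, "regions": sorted(s)})
        edge_list.sort(key=lambda e: e["pair"])
        return {
            "cell_type": self.cell_type,
            "marks": list(self.marks),
            "n_regions": self.n_regions,
            "threshold": self.threshold,
            "edges": edge_list,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CooccurrenceGraph":
        marks = tuple(d["marks"])
        idx = {m: i for i, m in enumerate(marks)}
        edges = {}
        for e in d["edges"]:
            a, b = (idx[m] for m in e["pair"])
            i, j = min(a, b), max(a, b)
            edges[(i, j)] = frozenset(int(r) for r in e["regions"])
        return cls(
            cell_type=d["cell_type"],
            marks=marks,
            n_regions=int(d["n_regions"]),
            threshold=float(d["threshold"]),
            edges=edges,
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, sort_keys=True, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "CooccurrenceGraph":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def _correlate(data: np.ndarray, method: str) -> np.ndarray:
    """Pairwise row correlations for a stack of region matrices.

    data: (N, K, B). Returns (N, K, K) with NaN where either row has zero
    variance and 1.0 on the diagonal.
    """
    if method == "spearman":
        data = rankdata(data, axis=2)
    x = data - data.mean(axis=2, keepdims=True)
    norms = np.sqrt((x * x).sum(axis=2))  # (N, K)
    cov = np.einsum("nkb,njb->nkj", x, x)
    denom = norms[:, :, None] * norms[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / denom
    corr[denom == 0] = np.nan
    np.clip(corr, -1.0, 1.0, out=corr)
    K = data.shape[1]
    corr[:, np.arange(K), np.arange(K)] = 1.0
    return corr


def region_correlations(
    tensor: RegionTensor, i: int, method: str = "pearson"
) -> np.ndarray:
    """K x K correlation matrix of region i's mark profiles.

    Entries involving a zero-variance row are NaN (undefined); the
    diagonal is 1 by convention.
    """
    if not 0 <= i < tensor.n_regions:
        raise IndexError(f"region {i} out of range [0, {tensor.n_regions})")
    return _correlate(tensor.data[i : i + 1], method)[0]


def all_correlations(tensor: RegionTensor, method: str = "pearson") -> np.ndarray:
    """(N, K, K) stack of per-region correlation matrices."""
    return _correlate(tensor.data, method)


def build_cooccurrence_graph(
    tensor: RegionTensor,
    threshold: float = DEFAULT_THRESHOLD,
    method: str = "pearson",
) -> CooccurrenceGraph:
    """Build the co-occurrence graph of one cell type.

    For each region i and unordered mark pair (j, k): if the correlation is
    defined and >= threshold (inclusive), region i joins the edge's region
    set. Edges whose set stays empty are omitted. NaN never passes the
    comparison, so undefined pairs are never coherent.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    corr = _correlate(tensor.data, method)
    K = tensor.n_marks
    edges: Dict[Tuple[int, int], FrozenSet[int]] = {}
    for j in range(K):
        for k in range(j + 1, K):
            with np.errstate(invalid="ignore"):
                hits = np.flatnonzero(corr[:, j, k] >= threshold)
            if hits.size:
                edges[(j, k)] = frozenset(int(r) for r in hits)
    return CooccurrenceGraph(
        cell_type=tensor.cell_type,
        marks=tensor.marks,
        n_regions=tensor.n_regions,
        threshold=threshold,
        edges=edges,
    )
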