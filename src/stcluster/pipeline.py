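"""Library-level orchestration of the full mining pipeline.

Composes the stages — tag counting, normalization, region assembly,
co-occurrence graphs, spatial and spatio-temporal mining — either from a
manifest of BED/bedGraph files on disk or from an in-memory simulated
dataset. The CLI subcommands are thin wrappers over these functions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .cograph import CooccurrenceGraph, build_cooccurrence_graph
from .genome import GenomeLayout
from .io import read_bed, read_manifest
from .preprocess import (
    BinnedTrack,
    RegionTensor,
    assemble_regions,
    bedgraph_to_counts,
    count_tags,
    normalize_track,
)
from .spatial import MiningParams, SpatialCluster, mine_spatial_clusters
from .synthetic import SimResult
from .temporal import SpatioTemporalCluster, mine_st_clusters

__all__ = [
    "tracks_from_manifest",
    "tracks_from_sim",
    "build_tensors",
    "build_graphs",
    "run_pipeline",
]


def tracks_from_manifest(
    manifest: pd.DataFrame | str | Path,
    layout: GenomeLayout,
    base_dir: str | Path | None = None,
    transform: str = "arcsine",
) -> Dict[str, List[BinnedTrack]]:
    """Bin, normalize and transform every (cell type, mark) in a manifest.

    Mark order follows manifest order and must be identical across cell
    types (one mark panel per run).
    """
    if not isinstance(manifest, pd.DataFrame):
        base_dir = Path(manifest).parent if base_dir is None else Path(base_dir)
        manifest = read_manifest(manifest)
    base = Path(base_dir) if base_dir is not None else Path(".")
    by_cell: Dict[str, List[BinnedTrack]] = {}
    for row in manifest.itertuples(index=False):
        path = base / row.path
        df = read_bed(path)
        if row.format == "bed":
            counts, total = count_tags(df, layout)
        else:
            counts, total = bedgraph_to_counts(df, layout)
        track = normalize_track(
            counts, total, cell_type=row.cell_type, mark=row.mark, transform=transform
        )
        by_cell.setdefault(row.cell_type, []).append(track)
    _check_mark_panels(by_cell)
    return by_cell


def tracks_from_sim(result: SimResult, transform: str = "arcsine") -> Dict[str, List[BinnedTrack]]:
    """Normalize the simulated per-bin counts directly (no file round trip)."""
    params = result.truth.params
    by_cell: Dict[str, List[BinnedTrack]] = {}
    for ct in params.cell_types:
        for mark in params.marks:
            counts = result.counts[(ct, mark)]
            track = normalize_track(
                counts, int(counts.sum()), cell_type=ct, mark=mark, transform=transform
            )
            by_cell.setdefault(ct, []).append(track)
    return by_cell


def _check_mark_panels(by_cell: Mapping[str, List[BinnedTrack]]) -> None:
    panels = {ct: tuple(t.mark for t in tracks) for ct, tracks in by_cell.items()}
    ref = next(iter(panels.values()))
    for ct, panel in panels.items():
        if panel != ref:
            raise ValueError(
                f"cell type {ct!r} has mark panel {panel}, expected {ref} "
                "(mark order must be identical across cell types)"
            )


def build_tensors(
    by_cell: Mapping[str, List[BinnedTrack]], layout: GenomeLayout
) -> Dict[str, RegionTensor]:
    return {ct: assemble_regions(tracks, layout) for ct, tracks in by_cell.items()}


def build_graphs(
    tensors: Mapping[str, RegionTensor],
    threshold: float = 0.9,
    method: str = "pearson",
) -> Dict[str, CooccurrenceGraph]:
    return {
        ct: build_cooccurrence_graph(t, threshold=threshold, method=method)
        for ct, t in tensors.items()
    }


def run_pipeline(
    result: SimResult,
    params: MiningParams | None = None,
    transform: str = "arcsine",
    method: str = "pearson",
) -> Tuple[
    Dict[str, RegionTensor],
    Dict[str, CooccurrenceGraph],
    Dict[str, List[SpatialCluster]],
    List[SpatioTemporalCluster],
]:
    """Run every stage on a simulated dataset; returns all intermediates."""
    params = params or MiningParams()
    by_cell = tracks_from_sim(result, transform=transform)
    tensors = build_tensors(by_cell, result.layout)
    graphs = build_graphs(tensors, threshold=params.threshold, method=method)
    spatial = {ct: mine_spatial_clusters(g, params) for ct, g in graphs.items()}
    order = list(result.truth.params.cell_types)
    st = mine_st_clusters([graphs[ct] for ct in order], params)
    return tensors, graphs, spatial, st
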