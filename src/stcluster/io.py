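"""File formats: BED tags, manifests, bin-resolution bedGraph, cluster tables.

All outputs are deterministic text: TSVs via pandas with fixed column
order, JSON with sorted keys, floats printed with ``%.17g`` so that
written tracks round-trip bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .spatial import SpatialCluster
from .temporal import SpatioTemporalCluster

__all__ = [
    "read_bed",
    "read_manifest",
    "write_bedgraph",
    "read_bedgraph",
    "write_spatial_clusters",
    "read_spatial_clusters",
    "write_st_clusters",
    "read_st_clusters",
]

MANIFEST_COLUMNS = ["cell_type", "mark", "path", "format"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file (tab-separated, 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}
    )
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the dataset manifest (TSV: cell_type, mark, path, format)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    bad = ~df["format"].isin(["bed", "bedgraph"])
    if bad.any():
        raise ValueError(
            f"{path}: unknown format(s) {sorted(df.loc[bad, 'format'].unique())}"
        )
    return df[MANIFEST_COLUMNS]


def write_bedgraph(values: np.ndarray, layout: GenomeLayout, path: str | Path) -> None:
    """Write one value per in-scope bin as a 4-column bedGraph."""
    values = np.asarray(values)
    if values.shape != (layout.total_bins,):
        raise ValueError("values length does not match layout")
    df = pd.DataFrame(
        {
            "chrom": layout.bin_chrom_names(),
            "start": layout.bin_starts(),
        }
    )
    df["end"] = df["start"] + layout.bin_size
    df["value"] = values
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.17g")


def read_bedgraph(path: str | Path, layout: GenomeLayout, strict: bool = True) -> np.ndarray:
    """Read a bin-resolution bedGraph back into a per-bin value vector.

    With ``strict`` each record must cover exactly one in-scope bin (the
    format :func:`write_bedgraph` emits); otherwise use
    :func:`stcluster.preprocess.bedgraph_to_counts` for arbitrary records.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    if df.shape[1] < 4:
        raise ValueError(f"{path}: bedGraph needs 4 columns")
    values = np.zeros(layout.total_bins, dtype=float)
    seen = np.zeros(layout.total_bins, dtype=bool)
    for chrom, start, end, val in zip(
        df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2], df.iloc[:, 3]
    ):
        loc = layout.locate(str(chrom), int(start))
        if loc is None:
            if strict:
                raise ValueError(f"{path}: record outside in-scope bins at {chrom}:{start}")
            continue
        gbin = loc[0]
        if strict and (int(end) - int(start)) != layout.bin_size:
            raise ValueError(f"{path}: record at {chrom}:{start} is not one bin wide")
        values[gbin] = float(val)
        seen[gbin] = True
    if strict and not seen.all():
        raise ValueError(f"{path}: {int((~seen).sum())} bins missing")
    return values


# ------------------------------------------------------------ cluster tables


def write_spatial_clusters(
    clusters: Sequence[SpatialCluster], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    """One row per cluster: cell_type, marks (;-joined), n_regions, regions."""
    rows = [
        {
            "cell_type": cl.cell_type,
            "marks": ";".join(cl.sorted_marks),
            "n_regions": len(cl.regions),
            "regions": ",".join(map(str, cl.sorted_regions)),
        }
        for cl in clusters
    ]
    pd.DataFrame(rows, columns=["cell_type", "marks", "n_regions", "regions"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([cl.to_json_dict() for cl in clusters], fh, sort_keys=True, indent=2)
            fh.write("\n")


def read_spatial_clusters(json_path: str | Path) -> List[SpatialCluster]:
    with open(json_path) as fh:
        data = json.load(fh)
    return [
        SpatialCluster(
            cell_type=d["cell_type"],
            marks=frozenset(d["marks"]),
            regions=frozenset(int(r) for r in d["regions"]),
        )
        for d in data
    ]


def write_st_clusters(
    clusters: Sequence[SpatioTemporalCluster],
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    rows = [
        {
            "marks": ";".join(cl.sorted_marks),
            "cell_types": ";".join(cl.sorted_cell_types),
            "n_regions": len(cl.regions),
            "regions": ",".join(map(str, cl.sorted_regions)),
        }
        for cl in clusters
    ]
    pd.DataFrame(rows, columns=["marks", "cell_types", "n_regions", "regions"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([cl.to_json_dict() for cl in clusters], fh, sort_keys=True, indent=2)
            fh.write("\n")


def read_st_clusters(json_path: str | Path) -> List[SpatioTemporalCluster]:
    with open(json_path) as fh:
        data = json.load(fh)
    return [
        SpatioTemporalCluster(
            marks=frozenset(d["marks"]),
            regions=frozenset(int(r) for r in d["regions"]),
            cell_types=frozenset(d["cell_types"]),
        )
        for d in data
    ]


def write_regions_bed(
    regions: Sequence[int], layout: GenomeLayout, path: str | Path
) -> None:
    """Member regions of a cluster as a BED3 file."""
    with open(path, "w") as fh:
        for r in sorted(regions):
            chrom, start, end = layout.region_bounds(r)
            fh.write(f"{chrom}\t{start}\t{end}\n")
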