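"""ChIP-seq signal transformation: tags -> binned, normalized tracks -> region tensors.

Each aligned tag is assigned to the single bin containing its midpoint.
Per-bin counts are converted to library proportions ``p = count / total``
and variance-stabilized with the arcsine transform ``arcsin(sqrt(p))``,
which damps spurious count noise and maps all values into ``[0, pi/2]``.
Tracks for the K marks of one cell type are then cut into N region
matrices ``R_i`` of shape K x B (marks x bins): the row vectors are the
contiguous local landscape of each modification, the columns the
combinatorial state of each bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genome import GenomeLayout

__all__ = [
    "BinnedTrack",
    "RegionTensor",
    "count_tags",
    "bedgraph_to_counts",
    "normalize_track",
    "assemble_regions",
]

logger = logging.getLogger(__name__)

IntervalInput = Union[pd.DataFrame, Iterable[Tuple[str, int, int]]]


@dataclass(frozen=True)
class BinnedTrack:
    """Normalized, transformed signal of one (cell type, mark) pair."""

    cell_type: str
    mark: str
    values: np.ndarray  # float, length = layout.total_bins
    total_tags: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class RegionTensor:
    """All region matrices of one cell type, stacked as ``data[N, K, B]``.

    ``data[i]`` is the region matrix R_i: row k is the slice of mark k's
    binned track over region i's B bins.
    """

    cell_type: str
    marks: Tuple[str, ...]
    layout: GenomeLayout
    data: np.ndarray  # shape (N, K, B)

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_marks(self) -> int:
        return self.data.shape[1]

    def region(self, i: int) -> np.ndarray:
        """The K x B matrix R_i."""
        if not 0 <= i < self.n_regions:
            raise IndexError(f"region {i} out of range [0, {self.n_regions})")
        return self.data[i]


def _intervals_to_arrays(intervals: IntervalInput):
    """Normalize interval input to (chrom, start, end, strand) numpy arrays.

    ``strand`` is None when the input has no strand column (BED3).
    """
    if isinstance(intervals, pd.DataFrame):
        df = intervals
        chrom = df.iloc[:, 0].to_numpy(dtype=object)
        start = df.iloc[:, 1].to_numpy(dtype=np.int64)
        end = df.iloc[:, 2].to_numpy(dtype=np.int64)
        strand = df.iloc[:, 5].to_numpy(dtype=object) if df.shape[1] >= 6 else None
        return chrom, start, end, strand
    recs = list(intervals)
    if not recs:
        return (
            np.empty(0, dtype=object),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            None,
        )
    chrom = np.array([r[0] for r in recs], dtype=object)
    start = np.array([r[1] for r in recs], dtype=np.int64)
    end = np.array([r[2] for r in recs], dtype=np.int64)
    strand = (
        np.array([r[5] for r in recs], dtype=object) if len(recs[0]) >= 6 else None
    )
    return chrom, start, end, strand


def count_tags(
    intervals: IntervalInput,
    layout: GenomeLayout,
    mode: str = "midpoint",
    shift: int = 0,
) -> Tuple[np.ndarray, int]:
    """Count tags per in-scope bin.

    Parameters
    ----------
    intervals
        BED-like records ``(chrom, start, end[, name, score, strand])`` —
        a DataFrame or an iterable of tuples. 0-based half-open.
    layout
        Binning geometry.
    mode
        ``"midpoint"`` (default): each tag hits the bin containing
        ``(start + end) // 2``. ``"five_prime"``: the strand-aware 5' end
        shifted ``shift`` bp toward the fragment center (``start + shift``
        on +, ``end - 1 - shift`` on -; unstranded records count as +).
    shift
        Shift in bp for ``five_prime`` mode.

    Returns
    -------
    (counts, total_tags)
        ``counts`` is an int64 vector over in-scope bins; ``total_tags``
        the number of counted tags. Tags on chromosomes absent from the
        layout are skipped with a warning; tags whose assigned position
        falls in a dropped partial region (or off the chromosome after
        shifting) are skipped silently. Neither enters ``total_tags``.
        A record with ``start >= end`` raises ``ValueError``.
    """
    chrom, start, end, strand = _intervals_to_arrays(intervals)
    counts = np.zeros(layout.total_bins, dtype=np.int64)
    if len(chrom) == 0:
        return counts, 0

    bad = start >= end
    if bad.any():
        idx = np.flatnonzero(bad)[:5]
        detail = "; ".join(
            f"record {i}: {chrom[i]}:{start[i]}-{end[i]}" for i in idx
        )
        raise ValueError(f"intervals with start >= end: {detail}")

    # map chromosome names to region offsets / in-scope bin counts
    B = layout.bins_per_region
    known = np.fromiter((layout.has_chrom(c) for c in chrom), dtype=bool, count=len(chrom))
    if not known.all():
        skipped = sorted({c for c in chrom[~known]})
        logger.warning(
            "skipping %d tags on unknown chromosomes: %s",
            int((~known).sum()),
            ", ".join(map(str, skipped)),
        )
    chrom, start, end = chrom[known], start[known], end[known]
    if strand is not None:
        strand = strand[known]
    if len(chrom) == 0:
        return counts, 0

    cid = np.fromiter(
        (layout._chrom_index[c] for c in chrom), dtype=np.int64, count=len(chrom)
    )
    offsets = np.asarray(layout._region_offsets, dtype=np.int64)
    inscope_bins = (offsets[cid + 1] - offsets[cid]) * B
    if mode == "midpoint":
        pos = (start + end) // 2
    elif mode == "five_prime":
        minus = (
            np.zeros(len(chrom), dtype=bool) if strand is None else (strand == "-")
        )
        pos = np.where(minus, end - 1 - shift, start + shift)
    else:
        raise ValueError(f"unknown tag-assignment mode {mode!r}")
    local_bin = pos // layout.bin_size
    ok = (pos >= 0) & (local_bin < inscope_bins)
    gbin = offsets[cid[ok]] * B + local_bin[ok]
    counts += np.bincount(gbin, minlength=layout.total_bins)
    return counts, int(ok.sum())


def bedgraph_to_counts(
    records: IntervalInput, layout: GenomeLayout, values: Sequence[float] | None = None
) -> Tuple[np.ndarray, float]:
    """Ingest pre-binned coverage (bedGraph) in place of raw tags.

    Each record's value is spread over the bins it overlaps, proportionally
    to overlap length, and the result is treated as a fractional tag count
    with ``total`` equal to the global sum of record values on resolvable
    chromosomes.

    ``records`` may be a 4-column DataFrame (chrom, start, end, value) or a
    3-column one with ``values`` passed separately.
    """
    if isinstance(records, pd.DataFrame) and values is None:
        if records.shape[1] < 4:
            raise ValueError("bedGraph input needs 4 columns (chrom, start, end, value)")
        values = records.iloc[:, 3].to_numpy(dtype=float)
    chrom, start, end, _ = _intervals_to_arrays(records)
    vals = np.asarray(values, dtype=float)
    counts = np.zeros(layout.total_bins, dtype=float)
    total = 0.0
    bs = layout.bin_size
    for c, s, e, v in zip(chrom, start, end, vals):
        if s >= e:
            raise ValueError(f"bedGraph record with start >= end: {c}:{s}-{e}")
        if not layout.has_chrom(c):
            continue
        total += float(v)
        span = e - s
        first = s // bs
        last = (e - 1) // bs
        for b in range(first, last + 1):
            ov_start = max(s, b * bs)
            ov_end = min(e, (b + 1) * bs)
            loc = layout.locate(c, ov_start)
            if loc is None:
                continue
            counts[loc[0]] += v * (ov_end - ov_start) / span
    return counts, total


def normalize_track(
    counts: np.ndarray,
    total_tags: float,
    cell_type: str = "",
    mark: str = "",
    transform: str = "arcsine",
) -> BinnedTrack:
    """Library-size normalize and variance-stabilize a raw count vector.

    ``arcsine``: value = arcsin(sqrt(count/total)), the standard arcsine
    variance-stabilizing transform for proportions, with the proportion
    clamped to [0, 1]. ``asinh``: value = asinh(count/total), offered for
    sensitivity analysis. A zero library (total_tags == 0) yields an
    all-zero track.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    if total_tags < 0:
        raise ValueError("negative total_tags")
    if total_tags == 0:
        vals = np.zeros_like(counts)
    else:
        p = np.clip(counts / total_tags, 0.0, 1.0)
        if transform == "arcsine":
            vals = np.arcsin(np.sqrt(p))
        elif transform == "asinh":
            vals = np.arcsinh(p)
        else:
            raise ValueError(f"unknown transform {transform!r}")
    return BinnedTrack(cell_type=cell_type, mark=mark, values=vals, total_tags=total_tags)


def assemble_regions(
    tracks: Sequence[BinnedTrack], layout: GenomeLayout
) -> RegionTensor:
    """Stack K binned tracks of one cell type into the (N, K, B) tensor.

    Mark order is the input order of ``tracks`` and must be identical
    across cell types within one analysis.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 marks (K >= 2)")
    cell_types = {t.cell_type for t in tracks}
    if len(cell_types) != 1:
        raise ValueError(f"tracks span multiple cell types: {sorted(cell_types)}")
    marks = tuple(t.mark for t in tracks)
    if len(set(marks)) != len(marks):
        raise ValueError("duplicate mark labels")
    for t in tracks:
        if t.values.shape != (layout.total_bins,):
            raise ValueError(
                f"track {t.mark!r} has {t.values.shape[0]} bins, "
                f"layout expects {layout.total_bins}"
            )
    stacked = np.stack([t.values for t in tracks])  # (K, total_bins)
    B = layout.bins_per_region
    data = stacked.reshape(len(tracks), layout.n_regions, B).transpose(1, 0, 2)
    return RegionTensor(
        cell_type=tracks[0].cell_type, marks=marks, layout=layout, data=np.ascontiguousarray(data)
    )
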