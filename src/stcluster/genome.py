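"""Genome binning geometry shared by every pipeline stage.

The genome is tiled with non-overlapping fixed-width bins (default 200 bp),
and consecutive runs of ``B`` bins form fixed-width regions (default 5 kb,
so ``B = 25``). Regions are the unit at which mark-mark correlation is
assessed; bins are the unit of signal. A trailing chromosome stub shorter
than one full region is dropped, so every region has exactly ``B`` bins.

Coordinates are 0-based, half-open (BED convention). Chromosome order is
input-file order, which fixes the global bin and region indexing and makes
all downstream output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = ["GenomeLayout", "load_chrom_sizes"]


class ChromSizesError(ValueError):
    """Raised for a malformed chrom.sizes file or inconsistent geometry."""


@dataclass(frozen=True)
class GenomeLayout:
    """Maps genomic coordinates to bin and region indices.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs; the order defines the global
        index space.
    bin_size
        Bin width in bp.
    region_size
        Region width in bp; must be an exact multiple of ``bin_size``.

    Only *in-scope* bins — those inside a complete region — receive global
    indices. Global bin index ``b`` belongs to region ``b // bins_per_region``.
    """

    chromosomes: Tuple[Tuple[str, int], ...]
    bin_size: int = 200
    region_size: int = 5000
    # derived, filled in __post_init__
    bins_per_region: int = field(init=False)
    _chrom_index: dict = field(init=False, repr=False)
    _region_offsets: Tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.region_size <= 0:
            raise ChromSizesError("bin_size and region_size must be positive")
        if self.region_size % self.bin_size != 0:
            raise ChromSizesError(
                f"region_size ({self.region_size}) is not a multiple of "
                f"bin_size ({self.bin_size})"
            )
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        if not chroms:
            raise ChromSizesError("no chromosomes given")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ChromSizesError("duplicate chromosome names")
        for n, l in chroms:
            if l <= 0:
                raise ChromSizesError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "bins_per_region", self.region_size // self.bin_size)
        offsets = [0]
        for _, length in chroms:
            offsets.append(offsets[-1] + length // self.region_size)
        object.__setattr__(self, "_region_offsets", tuple(offsets))
        object.__setattr__(
            self, "_chrom_index", {name: i for i, (name, _) in enumerate(chroms)}
        )

    # ------------------------------------------------------------------ sizes

    @property
    def n_regions(self) -> int:
        """Total number of complete regions N across all chromosomes."""
        return self._region_offsets[-1]

    @property
    def total_bins(self) -> int:
        """Number of in-scope bins (``n_regions * bins_per_region``)."""
        return self.n_regions * self.bins_per_region

    def chrom_n_regions(self, chrom: str) -> int:
        c = self._chrom_id(chrom)
        return self._region_offsets[c + 1] - self._region_offsets[c]

    def _chrom_id(self, chrom: str) -> int:
        try:
            return self._chrom_index[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._chrom_index

    # ----------------------------------------------------------------- lookup

    def locate(self, chrom: str, pos: int) -> Optional[Tuple[int, int]]:
        """Return ``(global_bin, region)`` for position ``pos`` on ``chrom``.

        Returns ``None`` when the position falls in a dropped trailing
        partial region. Raises ``KeyError`` for an unknown chromosome and
        ``ValueError`` for a position outside ``[0, length)``.
        """
        c = self._chrom_id(chrom)
        length = self.chromosomes[c][1]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside [0, {length}) on {chrom!r}")
        local_bin = pos // self.bin_size
        B = self.bins_per_region
        n_reg = self._region_offsets[c + 1] - self._region_offsets[c]
        if local_bin >= n_reg * B:
            return None
        gbin = self._region_offsets[c] * B + local_bin
        return gbin, gbin // B

    def region_bounds(self, region: int) -> Tuple[str, int, int]:
        """``(chrom, start, end)`` of a global region index, half-open bp."""
        if not 0 <= region < self.n_regions:
            raise IndexError(f"region {region} out of range [0, {self.n_regions})")
        c = int(np.searchsorted(self._region_offsets, region, side="right")) - 1
        local = region - self._region_offsets[c]
        start = local * self.region_size
        return self.chromosomes[c][0], start, start + self.region_size

    def bin_bounds(self, gbin: int) -> Tuple[str, int, int]:
        """``(chrom, start, end)`` of a global in-scope bin index."""
        if not 0 <= gbin < self.total_bins:
            raise IndexError(f"bin {gbin} out of range [0, {self.total_bins})")
        chrom, rstart, _ = self.region_bounds(gbin // self.bins_per_region)
        local = gbin % self.bins_per_region
        return chrom, rstart + local * self.bin_size, rstart + (local + 1) * self.bin_size

    # --------------------------------------------------- vectorized mapping

    def bin_chrom_names(self) -> np.ndarray:
        """Chromosome name for every in-scope bin, in global bin order."""
        B = self.bins_per_region
        parts = []
        for c, (name, _) in enumerate(self.chromosomes):
            n = (self._region_offsets[c + 1] - self._region_offsets[c]) * B
            parts.append(np.full(n, name, dtype=object))
        return np.concatenate(parts) if parts else np.empty(0, dtype=object)

    def bin_starts(self) -> np.ndarray:
        """Chromosome-local start coordinate of every in-scope bin."""
        B = self.bins_per_region
        parts = []
        for c in range(len(self.chromosomes)):
            n = (self._region_offsets[c + 1] - self._region_offsets[c]) * B
            parts.append(np.arange(n, dtype=np.int64) * self.bin_size)
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    def to_dict(self) -> dict:
        return {
            "chromosomes": [[n, l] for n, l in self.chromosomes],
            "bin_size": self.bin_size,
            "region_size": self.region_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeLayout":
        return cls(
            tuple((n, l) for n, l in d["chromosomes"]),
            bin_size=int(d["bin_size"]),
            region_size=int(d["region_size"]),
        )


def load_chrom_sizes(
    path: str | Path, bin_size: int = 200, region_size: int = 5000
) -> GenomeLayout:
    """Read a UCSC-style chrom.sizes file (tab-separated name, length).

    Chromosome order is file order. Blank lines are skipped; any other
    malformed line raises ``ChromSizesError`` naming the line number.
    """
    chroms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ChromSizesError(f"{path}:{lineno}: expected 'name<TAB>length'")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise ChromSizesError(
                    f"{path}:{lineno}: length {parts[1]!r} is not an integer"
                ) from None
            if length <= 0:
                raise ChromSizesError(f"{path}:{lineno}: non-positive length {length}")
            chroms.append((name, length))
    if not chroms:
        raise ChromSizesError(f"{path}: empty chrom.sizes file")
    return GenomeLayout(tuple(chroms), bin_size=bin_size, region_size=region_size)
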