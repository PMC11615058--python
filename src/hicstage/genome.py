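"""Genome binning: fixed-size partition of chromosomes into bins.

All coordinates are 0-based half-open; bin ``i`` of a chromosome covers
``[i*bin_size, (i+1)*bin_size)`` and the last bin may be short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BinnedGenome:
    """A fixed-size binning of an ordered set of chromosomes.

    Parameters
    ----------
    chrom_sizes : dict[str, int]
        Ordered mapping chromosome name -> length in bp.
    bin_size : int
        Bin width in bp.
    excluded : np.ndarray, optional
        Boolean mask over global bins (True = excluded from analysis,
        e.g. centromeric or sex-chromosome bins).
    """

    chrom_sizes: dict[str, int]
    bin_size: int
    excluded: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.chroms = list(self.chrom_sizes)
        self._n_bins_per_chrom = {
            c: -(-length // self.bin_size) for c, length in self.chrom_sizes.items()
        }
        self._offsets = {}
        off = 0
        for c in self.chroms:
            self._offsets[c] = off
            off += self._n_bins_per_chrom[c]
        self.n_bins = off
        if self.excluded is None:
            self.excluded = np.zeros(self.n_bins, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != (self.n_bins,):
                raise ValueError("excluded mask length does not match bin count")

    @classmethod
    def from_chrom_sizes_file(cls, path, bin_size: int) -> "BinnedGenome":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                         comment="#")
        return cls(dict(zip(df["chrom"], df["length"].astype(int))), bin_size)

    @classmethod
    def from_partition(cls, partition, bin_size: int) -> "BinnedGenome":
        """Build from a list of (chrom, n_bins) pairs (all bins full-width)."""
        return cls({c: n * bin_size for c, n in partition}, bin_size)

    def n_bins_of(self, chrom: str) -> int:
        return self._n_bins_per_chrom[chrom]

    def offset_of(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + self._n_bins_per_chrom[chrom])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of position ``pos`` on ``chrom``."""
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.chrom_sizes[chrom]):
            raise ValueError(
                f"position {pos} outside chromosome {chrom} "
                f"(length {self.chrom_sizes[chrom]})"
            )
        return self._offsets[chrom] + pos // self.bin_size

    def bin_location(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a global bin index."""
        if not (0 <= index < self.n_bins):
            raise IndexError(index)
        for c in self.chroms:
            off = self._offsets[c]
            n = self._n_bins_per_chrom[c]
            if index < off + n:
                local = index - off
                start = local * self.bin_size
                end = min(start + self.bin_size, self.chrom_sizes[c])
                return c, start, end
        raise IndexError(index)  # unreachable

    def bin_chrom_array(self) -> np.ndarray:
        """Chromosome name of every global bin."""
        out = np.empty(self.n_bins, dtype=object)
        for c in self.chroms:
            out[self.chrom_slice(c)] = c
        return out

    def bins_frame(self) -> pd.DataFrame:
        """BED-like table of all bins (chrom, start, end)."""
        rows = [self.bin_location(i) for i in range(self.n_bins)]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def same_partition(self, other: "BinnedGenome") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_sizes == other.chrom_sizes
        )
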