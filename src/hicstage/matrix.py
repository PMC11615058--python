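"""Symmetric binned contact matrices.

Counts are held as an upper-triangle sparse COO structure tied to a
:class:`~hicstage.genome.BinnedGenome`; dense symmetric views are produced on
demand (analyses here run at desk scale, a few thousand bins).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .genome import BinnedGenome


@dataclass
class ContactMatrix:
    """Symmetric non-negative contact matrix on a binned genome.

    ``data`` stores upper-triangle entries (i <= j) only; symmetry is by
    construction. ``raw`` distinguishes integer counts from balanced /
    normalized real-valued matrices.
    """

    genome: BinnedGenome
    data: sp.coo_matrix = field(repr=False)
    raw: bool = True

    @classmethod
    def from_dense(cls, genome: BinnedGenome, dense: np.ndarray, raw: bool = True
                   ) -> "ContactMatrix":
        dense = np.asarray(dense)
        if dense.shape != (genome.n_bins, genome.n_bins):
            raise ValueError("matrix shape does not match genome bin count")
        if not np.allclose(dense, dense.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(dense < 0):
            raise ValueError("contact matrix must be non-negative")
        upper = sp.coo_matrix(np.triu(dense))
        return cls(genome, upper, raw=raw)

    @classmethod
    def from_coo_arrays(cls, genome: BinnedGenome, i, j, v, raw: bool = True
                        ) -> "ContactMatrix":
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        v = np.asarray(v)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        m = sp.coo_matrix((v, (lo, hi)), shape=(genome.n_bins, genome.n_bins))
        m.sum_duplicates()
        return cls(genome, m, raw=raw)

    def toarray(self) -> np.ndarray:
        """Dense symmetric matrix (diagonal counted once)."""
        u = self.data.toarray()
        return u + np.triu(u, 1).T

    def intra_block(self, chrom: str) -> np.ndarray:
        s = self.genome.chrom_slice(chrom)
        return self.toarray()[s, s]

    def total(self) -> float:
        """Total contacts: each off-diagonal pair once plus diagonal."""
        return float(self.data.sum())

    def marginals(self) -> np.ndarray:
        return self.toarray().sum(axis=1)

    # ------------------------------------------------------------------ IO
    def write(self, prefix: str | Path) -> None:
        """Write as COO triplet TSV (bin_i, bin_j, count) + JSON sidecar."""
        prefix = Path(prefix)
        coo = self.data.tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(prefix.with_suffix(".coo.tsv"), "w") as fh:
            fh.write("bin_i\tbin_j\tcount\n")
            for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                if self.raw:
                    fh.write(f"{i}\t{j}\t{int(v)}\n")
                else:
                    fh.write(f"{i}\t{j}\t{v:.10g}\n")
        sidecar = {
            "bin_size": self.genome.bin_size,
            "chrom_sizes": self.genome.chrom_sizes,
            "raw": self.raw,
            "excluded_bins": np.flatnonzero(self.genome.excluded).tolist(),
        }
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, prefix: str | Path) -> "ContactMatrix":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        genome = BinnedGenome(
            {c: int(v) for c, v in sidecar["chrom_sizes"].items()},
            int(sidecar["bin_size"]),
        )
        genome.excluded[np.asarray(sidecar.get("excluded_bins", []), dtype=int)] = True
        rows, cols, vals = [], [], []
        with open(prefix.with_suffix(".coo.tsv")) as fh:
            header = fh.readline()
            assert header.startswith("bin_i")
            for line in fh:
                i, j, v = line.split("\t")
                rows.append(int(i))
                cols.append(int(j))
                vals.append(float(v))
        raw = bool(sidecar.get("raw", True))
        vals = np.asarray(vals)
        if raw:
            vals = vals.astype(np.int64)
        return cls.from_coo_arrays(genome, rows, cols, vals, raw=raw)
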