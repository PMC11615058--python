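"""Plain-text genomic track writers (bedGraph, BED, TSV)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import BinnedGenome


def write_bedgraph(genome: BinnedGenome, values: np.ndarray, path) -> None:
    """Per-bin track as bedGraph; NaN bins are skipped."""
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if not np.isfinite(v):
                continue
            chrom, start, end = genome.bin_location(i)
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] = ()) -> None:
    """BED3+ with optional extra columns."""
    cols = ["chrom", "start", "end", *extra_cols]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_genes_bed6(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "gene", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_genes_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene", "score", "strand"],
        dtype={"chrom": str},
    )
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


def write_chrom_sizes(genome: BinnedGenome, path) -> None:
    with open(path, "w") as fh:
        for c in genome.chroms:
            fh.write(f"{c}\t{genome.chrom_sizes[c]}\n")
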