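"""Read pairs to binned contact matrices.

Implements the standard Hi-C pair-level quality filters (dangling-end,
self-circle, re-ligation), binning into a fixed-resolution symmetric
matrix, cis/trans contact statistics, and the depth-based resolution
assessment (smallest bin size at which >80% of bins collect >=1,000
contacts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .matrix import ContactMatrix

VALID = "valid"
DANGLING_END = "dangling_end"
SELF_CIRCLE = "self_circle"
RE_LIGATION = "re_ligation"
PAIR_CLASSES = (VALID, DANGLING_END, SELF_CIRCLE, RE_LIGATION)

CIS_LONG_THRESHOLD = 20_000  # bp; boundary between short- and long-range cis


@dataclass
class ContactStats:
    """Pair-level bookkeeping of a binning run."""

    total_pairs: int
    valid_pairs: int
    cis_fraction: float
    trans_fraction: float
    cis_long_fraction: float  # cis pairs at distance > 20 kb
    per_bin_coverage: np.ndarray
    class_counts: dict


def classify_pair(
    chrom1, pos1, strand1, frag1, chrom2, pos2, strand2, frag2
) -> str:
    """Classify one annotated read pair.

    Same fragment with inward-facing strands (leftmost mate on '+') is a
    dangling end; same fragment outward-facing is a self-circle; adjacent
    fragments on one chromosome are a re-ligation; everything else is
    valid. Follows the community (Juicer-style) conventions.
    """
    if frag1 is None or frag2 is None or (
        isinstance(frag1, float) and np.isnan(frag1)
    ):
        raise ValueError(
            "fragment annotation missing; use position-only mode "
            "(all pairs valid) via bin_contacts(keep_only_valid=False)"
        )
    if chrom1 == chrom2:
        f1, f2 = int(frag1), int(frag2)
        if f1 == f2:
            if pos1 <= pos2:
                left_strand, right_strand = strand1, strand2
            else:
                left_strand, right_strand = strand2, strand1
            if (left_strand, right_strand) == ("+", "-"):
                return DANGLING_END
            if (left_strand, right_strand) == ("-", "+"):
                return SELF_CIRCLE
            return VALID  # tandem strands on one fragment: kept
        if abs(f1 - f2) == 1:
            return RE_LIGATION
    return VALID


def classify_pairs(pairs: pd.DataFrame) -> pd.Series:
    """Vectorized classification of a pair table; partitions every pair."""
    has_frags = "frag1" in pairs.columns and "frag2" in pairs.columns
    if not has_frags or pairs[["frag1", "frag2"]].isna().any().any():
        raise ValueError(
            "fragment annotation missing; use position-only mode "
            "(all pairs valid)"
        )
    same_chrom = pairs["chrom1"].to_numpy() == pairs["chrom2"].to_numpy()
    f1 = pairs["frag1"].to_numpy(dtype=np.int64)
    f2 = pairs["frag2"].to_numpy(dtype=np.int64)
    p1 = pairs["pos1"].to_numpy()
    p2 = pairs["pos2"].to_numpy()
    s1 = pairs["strand1"].to_numpy()
    s2 = pairs["strand2"].to_numpy()
    left_s = np.where(p1 <= p2, s1, s2)
    right_s = np.where(p1 <= p2, s2, s1)
    out = np.full(len(pairs), VALID, dtype=object)
    same_frag = same_chrom & (f1 == f2)
    out[same_frag & (left_s == "+") & (right_s == "-")] = DANGLING_END
    out[same_frag & (left_s == "-") & (right_s == "+")] = SELF_CIRCLE
    out[same_chrom & (np.abs(f1 - f2) == 1)] = RE_LIGATION
    return pd.Series(out, index=pairs.index, name="pair_class")


def bin_contacts(
    pairs: pd.DataFrame,
    genome: BinnedGenome,
    keep_only_valid: bool = False,
) -> tuple[ContactMatrix, ContactStats]:
    """Bin read pairs into a symmetric contact matrix.

    Each kept pair increments exactly one upper-triangle (i <= j) entry.
    With ``keep_only_valid`` the fragment-based filters are applied and
    dropped pairs are tallied in the returned :class:`ContactStats`.
    """
    for chrom_col, pos_col in (("chrom1", "pos1"), ("chrom2", "pos2")):
        chroms = pairs[chrom_col]
        unknown = set(chroms.unique()) - set(genome.chrom_sizes)
        if unknown:
            raise ValueError(f"pairs reference unknown chromosomes: {sorted(unknown)}")
        lengths = chroms.map(genome.chrom_sizes).to_numpy()
        bad = (pairs[pos_col].to_numpy() < 0) | (pairs[pos_col].to_numpy() >= lengths)
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"pair position beyond chromosome length at row {k}: "
                f"{pairs.iloc[k].to_dict()}"
            )

    if keep_only_valid:
        classes = classify_pairs(pairs)
        class_counts = classes.value_counts().to_dict()
        kept = pairs[classes == VALID]
    else:
        class_counts = {VALID: len(pairs)}
        kept = pairs
    for c in PAIR_CLASSES:
        class_counts.setdefault(c, 0)

    offsets = {c: genome.offset_of(c) for c in genome.chroms}
    b1 = (
        kept["chrom1"].map(offsets).to_numpy(dtype=np.int64)
        + kept["pos1"].to_numpy(dtype=np.int64) // genome.bin_size
    )
    b2 = (
        kept["chrom2"].map(offsets).to_numpy(dtype=np.int64)
        + kept["pos2"].to_numpy(dtype=np.int64) // genome.bin_size
    )
    matrix = ContactMatrix.from_coo_arrays(
        genome, b1, b2, np.ones(len(kept), dtype=np.int64), raw=True
    )
    stats = _pair_stats(kept, genome, len(pairs), class_counts)
    return matrix, stats


def _pair_stats(kept: pd.DataFrame, genome: BinnedGenome, total: int,
                class_counts: dict) -> ContactStats:
    if len(kept) == 0:
        raise ValueError("zero valid pairs")
    cis = kept["chrom1"].to_numpy() == kept["chrom2"].to_numpy()
    n_cis = int(cis.sum())
    dist = np.abs(
        kept["pos1"].to_numpy(dtype=np.int64) - kept["pos2"].to_numpy(dtype=np.int64)
    )[cis]
    n_long = int((dist > CIS_LONG_THRESHOLD).sum())
    offsets = {c: genome.offset_of(c) for c in genome.chroms}
    cov = np.zeros(genome.n_bins)
    for chrom_col, pos_col in (("chrom1", "pos1"), ("chrom2", "pos2")):
        b = (
            kept[chrom_col].map(offsets).to_numpy(dtype=np.int64)
            + kept[pos_col].to_numpy(dtype=np.int64) // genome.bin_size
        )
        np.add.at(cov, b, 1)
    return ContactStats(
        total_pairs=total,
        valid_pairs=len(kept),
        cis_fraction=n_cis / len(kept),
        trans_fraction=1.0 - n_cis / len(kept),
        cis_long_fraction=n_long / n_cis if n_cis else float("nan"),
        per_bin_coverage=cov,
        class_counts=class_counts,
    )


def contact_stats(pairs: pd.DataFrame, genome: BinnedGenome) -> ContactStats:
    """Cis/trans and long-range statistics of a pair table (no filtering)."""
    if len(pairs) == 0:
        raise ValueError("zero valid pairs")
    return _pair_stats(pairs, genome, len(pairs),
                       {c: (len(pairs) if c == VALID else 0) for c in PAIR_CLASSES})


def drop_exact_duplicates(pairs: pd.DataFrame) -> pd.DataFrame:
    """Optional exact-duplicate filter (same chrom/pos/strand both mates)."""
    return pairs.drop_duplicates(
        subset=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    ).reset_index(drop=True)


def resolution_assessment(
    pairs: pd.DataFrame,
    chrom_sizes: dict,
    bin_sizes: list[int],
    min_reads: int = 1000,
    min_fraction: float = 0.80,
) -> tuple[pd.DataFrame, int | None]:
    """Fraction of bins with >= ``min_reads`` marginal contacts per bin size.

    The optimal resolution is the smallest bin size whose fraction exceeds
    ``min_fraction`` (None when no size qualifies).
    """
    if not bin_sizes:
        raise ValueError("bin_sizes must be non-empty")
    if sorted(bin_sizes) != list(bin_sizes):
        raise ValueError("bin_sizes must be sorted ascending")
    rows = []
    optimal = None
    for bs in bin_sizes:
        genome = BinnedGenome(chrom_sizes, bs)
        if len(pairs):
            _, stats = bin_contacts(pairs, genome, keep_only_valid=False)
            cov = stats.per_bin_coverage[~genome.excluded]
        else:
            cov = np.zeros(np.sum(~genome.excluded))
        frac = float(np.mean(cov >= min_reads)) if len(cov) else 0.0
        rows.append({"bin_size": bs, "fraction_covered": frac})
        if optimal is None and frac > min_fraction:
            optimal = bs
    return pd.DataFrame(rows), optimal
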