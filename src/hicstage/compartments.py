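"""A/B compartment analysis.

Compartments are called per chromosome from the first principal component
of the correlation matrix of the distance-normalized (observed/expected)
contact map: bins with positive PC1 form the active A compartment, negative
the inactive B, with the sign oriented so that PC1 correlates positively
with GC content. An A-B index quantifies, per bin, the balance of contact
mass with A- versus B-labeled bins, and two stage profiles are compared
bin-by-bin to produce a switch table (AA / BB / A->B / B->A) with merged
regions and embedded genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .matrix import ContactMatrix

logger = logging.getLogger(__name__)

EXCLUDED = "excluded"


@dataclass
class CompartmentProfile:
    """Per-bin PC1, A/B/excluded label, optional A-B index."""

    genome: BinnedGenome
    pc1: np.ndarray  # NaN on excluded bins
    labels: np.ndarray  # 'A' / 'B' / 'excluded'
    oriented: bool
    ab_index: np.ndarray = field(default=None)

    def included(self) -> np.ndarray:
        return self.labels != EXCLUDED

    def fractions(self) -> dict[str, float]:
        inc = self.included()
        n = int(inc.sum())
        return {
            "A": float(np.sum(self.labels == "A")) / n if n else float("nan"),
            "B": float(np.sum(self.labels == "B")) / n if n else float("nan"),
        }


@dataclass
class SwitchTable:
    """Per-bin switch class with merged regions and embedded genes."""

    classes: np.ndarray  # 'AA'/'BB'/'AB'/'BA'/'excluded'
    regions: pd.DataFrame  # chrom, start, end, class
    fractions: dict
    genes_by_class: dict


# ---------------------------------------------------------------- expected
def expected_marginal(matrix: ContactMatrix) -> np.ndarray:
    """Marginal-product expected map: E_ij = f_i f_j T, f_i = marg_i / T.

    This is the coverage-driven background used for inter-chromosomal
    normalization; it cannot remove distance decay.
    """
    dense = matrix.toarray().astype(float)
    total = dense.sum()
    if total == 0:
        raise ValueError("zero-total matrix has no expected model")
    f = dense.sum(axis=1) / total
    return np.outer(f, f) * total


def expected_distance(matrix: ContactMatrix) -> dict[str, np.ndarray]:
    """Per-chromosome mean observed contact at each bin distance.

    expected[c][d] is the mean over all included intra-chromosomal pairs of
    chromosome c at distance d (excluded bins are left out of the mean).
    """
    g = matrix.genome
    dense = matrix.toarray().astype(float)
    out = {}
    for c in g.chroms:
        s = g.chrom_slice(c)
        block = dense[s, s]
        inc = ~g.excluded[s]
        n = block.shape[0]
        exp = np.zeros(n)
        for d in range(n):
            i = np.arange(n - d)
            keep = inc[i] & inc[i + d]
            if keep.any():
                exp[d] = block[i[keep], i[keep] + d].mean()
        out[c] = exp
    return out


def oe_and_correlation(
    block: np.ndarray, expected: np.ndarray, include: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """O/E-transform one intra block and return its Pearson correlation.

    Rows of excluded bins are dropped before correlating; rows whose O/E
    profile is constant (zero variance) are dropped too and logged.
    Returns (oe matrix, correlation matrix, indices of kept bins).
    """
    n = block.shape[0]
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp = expected[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, block / exp, 0.0)
    kept = np.flatnonzero(include)
    sub = oe[np.ix_(kept, kept)].copy()
    # the self-contact diagonal carries no compartment signal: replace it
    # with each row's off-diagonal mean so uniform maps stay degenerate
    k = sub.shape[0]
    if k > 1:
        off_mean = (sub.sum(axis=1) - np.diag(sub)) / (k - 1)
        sub[np.arange(k), np.arange(k)] = off_mean
    sd = sub.std(axis=1)
    constant = sd <= 1e-10 * np.maximum(1.0, np.abs(sub.mean(axis=1)))
    if constant.any():
        logger.info("dropping %d constant O/E rows", int(constant.sum()))
        kept = kept[~constant]
        sub = sub[np.ix_(~constant, ~constant)]
    if len(kept) < 2:
        raise ValueError("too few usable bins for a correlation matrix")
    corr = np.corrcoef(sub)
    np.fill_diagonal(corr, 1.0)
    return oe, corr, kept


# --------------------------------------------------------------------- PC1
def pc1_of_correlation(corr: np.ndarray) -> np.ndarray:
    """Leading principal component loading of a correlation matrix.

    Columns are centered and the unit leading eigenvector of the resulting
    covariance structure is returned (one loading per bin).
    """
    xc = corr - corr.mean(axis=0, keepdims=True)
    s = xc.T @ xc
    vals, vecs = np.linalg.eigh(s)
    v = vecs[:, -1]
    return v


def call_compartments(
    matrix: ContactMatrix, gc: np.ndarray = None
) -> CompartmentProfile:
    """Call A/B compartments per chromosome from a balanced matrix.

    For each chromosome: distance-decay expected, O/E, Pearson correlation
    over included bins, PC1 of the centered correlation matrix; the sign is
    flipped so PC1 correlates non-negatively with GC content when GC is
    supplied (otherwise the raw sign is kept and the profile is flagged
    unoriented). Bins excluded by the genome mask (centromeres, sex
    chromosomes) and zero-coverage bins never receive a label.
    """
    g = matrix.genome
    dense = matrix.toarray().astype(float)
    expected = expected_distance(matrix)
    pc1 = np.full(g.n_bins, np.nan)
    labels = np.full(g.n_bins, EXCLUDED, dtype="U8")
    for c in g.chroms:
        s = g.chrom_slice(c)
        block = dense[s, s]
        include = (~g.excluded[s]) & (block.sum(axis=1) > 0)
        if include.sum() < 3:
            logger.warning("chromosome %s has too few usable bins; skipped", c)
            continue
        try:
            _, corr, kept = oe_and_correlation(block, expected[c], include)
        except ValueError:
            warnings.warn(
                f"degenerate partition on {c}: O/E carries no compartment "
                "signal; no labels assigned"
            )
            continue
        v = pc1_of_correlation(corr)
        if gc is not None:
            gc_sub = np.asarray(gc)[s][kept]
            if np.std(gc_sub) > 0 and np.corrcoef(v, gc_sub)[0, 1] < 0:
                v = -v
        pc1[s.start + kept] = v
        lab = np.where(v > 0, "A", "B")
        labels[s.start + kept] = lab
        if len(set(lab)) == 1:
            warnings.warn(
                f"degenerate compartment partition on {c}: all bins {lab[0]}"
            )
    return CompartmentProfile(g, pc1, labels, oriented=gc is not None)


def ab_index(matrix: ContactMatrix, profile: CompartmentProfile) -> np.ndarray:
    """Per-bin (contacts with A - contacts with B) / total contacts.

    Positive values mean A-leaning contact preference; isolated bins (zero
    contact mass with labeled bins) are NaN.
    """
    dense = matrix.toarray().astype(float)
    a_mask = profile.labels == "A"
    b_mask = profile.labels == "B"
    a_sum = dense[:, a_mask].sum(axis=1)
    b_sum = dense[:, b_mask].sum(axis=1)
    tot = a_sum + b_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(tot > 0, (a_sum - b_sum) / tot, np.nan)
    idx[~profile.included()] = np.nan
    return idx


# ----------------------------------------------------------------- switches
def detect_switches(
    profile_1: CompartmentProfile,
    profile_2: CompartmentProfile,
    min_abs_delta: float = None,
    gene_annotation: pd.DataFrame = None,
) -> SwitchTable:
    """Classify each bin as AA / BB / A->B ('AB') / B->A ('BA').

    A switch requires a PC1 sign change AND |PC1_1 - PC1_2| >=
    ``min_abs_delta`` (default 0.4 x the stage-1 PC1 standard deviation), a
    transparent variability filter; sign changes below the delta keep their
    stage-1 class. Runs of one class are merged into regions and genes
    whose body overlaps a region are listed under its class.
    """
    if not (profile_1.oriented and profile_2.oriented):
        raise ValueError("both profiles must be sign-oriented before comparison")
    g = profile_1.genome
    if not g.same_partition(profile_2.genome):
        raise ValueError("profiles must share one genome partition")
    p1, p2 = profile_1.pc1, profile_2.pc1
    if min_abs_delta is None:
        min_abs_delta = 0.4 * float(np.nanstd(p1))
    both = profile_1.included() & profile_2.included()
    classes = np.full(g.n_bins, EXCLUDED, dtype="U8")
    delta_ok = np.abs(p1 - p2) >= min_abs_delta
    a1 = p1 > 0
    a2 = p2 > 0
    classes[both & a1 & ~a2 & delta_ok] = "AB"
    classes[both & ~a1 & a2 & delta_ok] = "BA"
    classes[both & a1 & (classes == EXCLUDED)] = "AA"
    classes[both & ~a1 & (classes == EXCLUDED)] = "BB"

    classified = classes != EXCLUDED
    n = int(classified.sum())
    fractions = {
        k: float(np.sum(classes == k)) / n if n else float("nan")
        for k in ("AA", "BB", "AB", "BA")
    }
    regions = _merge_runs(classes, g)
    genes_by_class = {k: [] for k in ("AA", "BB", "AB", "BA")}
    if gene_annotation is not None:
        for _, r in regions.iterrows():
            hit = gene_annotation[
                (gene_annotation["chrom"] == r["chrom"])
                & (gene_annotation["start"] < r["end"])
                & (gene_annotation["end"] > r["start"])
            ]
            genes_by_class[r["class"]].extend(hit["gene"].tolist())
        genes_by_class = {k: sorted(set(v)) for k, v in genes_by_class.items()}
    return SwitchTable(classes, regions, fractions, genes_by_class)


def _merge_runs(classes: np.ndarray, g: BinnedGenome) -> pd.DataFrame:
    rows = []
    for c in g.chroms:
        s = g.chrom_slice(c)
        sub = classes[s]
        start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or sub[i] != sub[start]:
                if sub[start] != EXCLUDED:
                    rows.append(
                        (
                            c,
                            start * g.bin_size,
                            min(i * g.bin_size, g.chrom_sizes[c]),
                            sub[start],
                        )
                    )
                start = i
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])
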