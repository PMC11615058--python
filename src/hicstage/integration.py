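"""Cross-layer integration of compartments, TADs, PEIs and expression.

Joins gene-level expression (FPKM) onto the chromatin layers and computes
the comparative statistics: Spearman correlation of expression with GC
content (permutation p), A-vs-B expression contrast (rank-sum test, no
built-in directional assertion), the three-way overlap of dynamic genes
(compartment switch / differential TAD / differential expression), and
relative qPCR quantification by the 2^-ddCt method. All joins are
loss-accounted: dropped genes are counted, never silently discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from .compartments import CompartmentProfile

logger = logging.getLogger(__name__)


# ------------------------------------------------------------- correlations
def gc_expression_correlation(
    expression: pd.DataFrame,
    genes_with_gc: pd.DataFrame,
    fpkm_col: str = "fpkm",
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation of log1p(FPKM) with gene GC content.

    Significance is a two-sided permutation p over ``n_perm`` seeded
    shuffles of the pairing. No sign is asserted; active compartments tend
    to be GC-rich while genome-wide gene-level trends can run either way.
    """
    merged = expression.merge(genes_with_gc[["gene", "gc"]], on="gene")
    if len(merged) < 10:
        raise ValueError("need >= 10 genes with both expression and GC")
    gc = merged["gc"].to_numpy(dtype=float)
    if np.all(gc == gc[0]):
        raise ValueError("GC content is constant; correlation undefined")
    x = np.log1p(merged[fpkm_col].to_numpy(dtype=float))
    rho = float(spearmanr(x, gc).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = spearmanr(x, rng.permutation(gc)).statistic
    p = (1 + np.sum(np.abs(null) >= abs(rho))) / (n_perm + 1)
    return rho, float(p)


@dataclass
class CompartmentContrast:
    median_a: float
    median_b: float
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    n_dropped: int


def compartment_expression_contrast(
    expression: pd.DataFrame,
    profile: CompartmentProfile,
    genes: pd.DataFrame,
    fpkm_col: str = "fpkm",
) -> CompartmentContrast:
    """A-vs-B expression contrast by TSS-bin compartment assignment.

    Genes whose TSS bin is excluded are dropped and counted. Reports the
    median log1p(FPKM) per compartment and a two-sided Mann-Whitney
    rank-sum test; the caller interprets the direction.
    """
    g = profile.genome
    merged = expression.merge(genes[["gene", "chrom", "tss"]], on="gene")
    bins = np.array(
        [g.bin_index(c, t) for c, t in zip(merged["chrom"], merged["tss"])]
    )
    labels = profile.labels[bins]
    keep = labels != "excluded"
    n_dropped = int((~keep).sum()) + (len(expression) - len(merged))
    vals = np.log1p(merged[fpkm_col].to_numpy(dtype=float))[keep]
    labs = labels[keep]
    a = vals[labs == "A"]
    b = vals[labs == "B"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a compartment has no assigned genes")
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return CompartmentContrast(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        statistic=float(stat),
        p_value=float(p),
        n_a=len(a),
        n_b=len(b),
        n_dropped=n_dropped,
    )


# ------------------------------------------------------------------- DE/Venn
def differential_expression_flags(
    expression: pd.DataFrame,
    col_1: str = "fpkm_gv",
    col_2: str = "fpkm_mii",
    min_abs_log2fc: float = 1.0,
) -> pd.Series:
    """Differential flag: |log2((FPKM2+1)/(FPKM1+1))| >= threshold."""
    lfc = np.log2((expression[col_2] + 1.0) / (expression[col_1] + 1.0))
    return pd.Series(
        np.abs(lfc) >= min_abs_log2fc, index=expression.index, name="de"
    )


@dataclass
class VennCounts:
    """All 7 intersection regions of three gene sets."""

    only_switch: int
    only_tad: int
    only_de: int
    switch_tad: int
    switch_de: int
    tad_de: int
    triple: int
    triple_genes: list

    def totals(self) -> dict:
        return {
            "switch": self.only_switch + self.switch_tad + self.switch_de
            + self.triple,
            "tad": self.only_tad + self.switch_tad + self.tad_de + self.triple,
            "de": self.only_de + self.switch_de + self.tad_de + self.triple,
        }


def dynamic_gene_overlap(
    switch_genes, tad_genes, de_genes
) -> VennCounts:
    """Exact three-way set algebra of dynamic gene lists."""
    s, t, d = set(switch_genes), set(tad_genes), set(de_genes)
    nonempty = [x for x in (s, t, d) if x]
    if len(nonempty) >= 2:
        for i, x in enumerate(nonempty):
            for y in nonempty[i + 1:]:
                if not (x & y) and x and y:
                    logger.warning(
                        "two nonempty dynamic gene sets share no IDs; "
                        "check identifier namespaces"
                    )
                    break
    triple = s & t & d
    return VennCounts(
        only_switch=len(s - t - d),
        only_tad=len(t - s - d),
        only_de=len(d - s - t),
        switch_tad=len((s & t) - d),
        switch_de=len((s & d) - t),
        tad_de=len((t & d) - s),
        triple=len(triple),
        triple_genes=sorted(triple),
    )


# --------------------------------------------------------------------- qPCR
def ddct(
    qpcr: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
) -> pd.DataFrame:
    """Relative quantification by the 2^-ddCt method.

    qPCR table columns: group, gene, ct (one row per replicate). Per group,
    dCt = mean Ct(target) - mean Ct(reference); ddCt = dCt(group) -
    dCt(calibrator); fold = 2^-ddCt. The calibrator group's fold is 1 by
    construction, and adding a constant to every Ct of a group leaves the
    folds unchanged.
    """
    if (qpcr["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    groups = qpcr["group"].unique()
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    mean_ct = qpcr.groupby(["group", "gene"])["ct"].mean()
    for grp in groups:
        if (grp, reference_gene) not in mean_ct.index:
            raise ValueError(
                f"reference gene {reference_gene!r} missing in group {grp!r}"
            )
    rows = []
    targets = [g for g in qpcr["gene"].unique() if g != reference_gene]
    for gene in targets:
        d_cal = (
            mean_ct[(calibrator_group, gene)]
            - mean_ct[(calibrator_group, reference_gene)]
        )
        for grp in groups:
            if (grp, gene) not in mean_ct.index:
                continue
            d = mean_ct[(grp, gene)] - mean_ct[(grp, reference_gene)]
            ddc = d - d_cal
            rows.append(
                {
                    "group": grp,
                    "gene": gene,
                    "delta_ct": float(d),
                    "delta_delta_ct": float(ddc),
                    "fold_change": float(2.0 ** (-ddc)),
                }
            )
    return pd.DataFrame(rows)
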