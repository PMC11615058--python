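"""Promoter-enhancer interaction (PEI) calling.

Promoter windows span 2,000 bp upstream to 500 bp downstream of the TSS
(strand-relative). For every promoter bin, candidate partner bins within a
scanning span on the same chromosome are tested against a domain-aware
expected model: within each TAD (and for a per-chromosome background) a
power law log(expected) = a + alpha*log(distance) is fit by least squares,
and the upper-tail Poisson probability of the observed count given the
fitted expected is corrected across all tests by Benjamini-Hochberg.
Called PEIs must satisfy FDR q < 0.01, distance >= 15 kb, and observed >
expected. Summary statistics (within-TAD fraction, short-range fraction,
promoter-skipping fraction, per-gene counts) and a two-stage per-gene
delta table complete the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .genome import BinnedGenome
from .matrix import ContactMatrix
from .tads import TADSet

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500


def scale_to_depth(matrix: ContactMatrix, total: float) -> ContactMatrix:
    """Rescale a balanced matrix so its entries sum to ``total``.

    Balancing to row sums 1 destroys the count scale the Poisson test
    needs; rescaling to the raw sequencing depth restores it while keeping
    the bias correction.
    """
    cur = matrix.total()
    if cur <= 0:
        raise ValueError("cannot rescale an empty matrix")
    dense = matrix.toarray() * (total / cur)
    return ContactMatrix.from_dense(matrix.genome, dense, raw=False)


def make_promoters(genes: pd.DataFrame, genome: BinnedGenome) -> pd.DataFrame:
    """Promoter windows ([TSS-2000, TSS+500] on '+', mirrored on '-').

    Windows are clipped to the chromosome; ``bins`` holds the global bin
    indices the window overlaps at the working resolution.
    """
    rows = []
    for _, r in genes.iterrows():
        chrom = r["chrom"]
        if chrom not in genome.chrom_sizes:
            logger.warning("promoter for %s on unknown chromosome %s; skipped",
                           r["gene"], chrom)
            continue
        tss = int(r["tss"]) if "tss" in r else int(r["start"])
        length = genome.chrom_sizes[chrom]
        if r["strand"] == "+":
            lo, hi = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
        else:
            lo, hi = tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM
        lo, hi = max(0, lo), min(length, hi)
        b_lo = genome.bin_index(chrom, lo)
        b_hi = genome.bin_index(chrom, hi - 1)
        rows.append(
            {
                "gene": r["gene"],
                "chrom": chrom,
                "tss": tss,
                "strand": r["strand"],
                "win_start": lo,
                "win_end": hi,
                "bins": list(range(b_lo, b_hi + 1)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DomainBackground:
    """Two-level expected model: per-TAD power-law fits over a per-chromosome
    background fit. ``alpha`` values are the fitted decay exponents."""

    genome: BinnedGenome
    domain_fits: list  # (start_bin, end_bin, a, alpha)
    chrom_fits: dict  # chrom -> (a, alpha)

    def expected(self, i: int, j: int) -> float:
        lo, hi = (i, j) if i <= j else (j, i)
        d = hi - lo
        if d == 0:
            return np.nan
        for a, b, inter, alpha in self.domain_fits:
            if a <= lo and hi <= b:
                return float(np.exp(inter + alpha * np.log(d)))
        chrom, _, _ = self.genome.bin_location(lo)
        inter, alpha = self.chrom_fits[chrom]
        return float(np.exp(inter + alpha * np.log(d)))

    def expected_vector(self, pb: int, js: np.ndarray) -> np.ndarray:
        """Vectorized expected for one promoter bin against candidate bins."""
        js = np.asarray(js)
        d = np.abs(js - pb).astype(float)
        chrom, _, _ = self.genome.bin_location(pb)
        inter, alpha = self.chrom_fits[chrom]
        with np.errstate(divide="ignore"):
            out = np.exp(inter + alpha * np.log(d))
        out[d == 0] = np.nan
        for a, b, dom_inter, dom_alpha in self.domain_fits:
            if a <= pb < b:
                inside = (js >= a) & (js < b) & (d > 0)
                out[inside] = np.exp(dom_inter + dom_alpha * np.log(d[inside]))
                break
        return out


def _power_law_fit(block: np.ndarray) -> tuple[float, float] | None:
    """LS fit of log(mean count) vs log(bin distance); None if < 3 points."""
    n = block.shape[0]
    ds, means = [], []
    for d in range(1, n):
        vals = np.diagonal(block, offset=d)
        if vals.size and vals.mean() > 0:
            ds.append(d)
            means.append(vals.mean())
    if len(ds) < 3:
        return None
    x = np.log(np.asarray(ds, dtype=float))
    y = np.log(np.asarray(means))
    alpha, inter = np.polyfit(x, y, 1)
    return float(inter), float(alpha)


def fit_domain_background(matrix: ContactMatrix, tads: TADSet
                          ) -> DomainBackground:
    """Fit the domain-aware expected model.

    Each TAD gets its own log-log power-law fit of mean contact count
    against bin distance; pairs outside every TAD (or in TADs with fewer
    than 3 occupied distances, which fall back with a log message) use the
    per-chromosome background fit.
    """
    g = matrix.genome
    dense = matrix.toarray().astype(float)
    chrom_fits = {}
    for c in g.chroms:
        s = g.chrom_slice(c)
        fit = _power_law_fit(dense[s, s])
        if fit is None:
            fit = (np.log(max(dense[s, s].mean(), 1e-12)), 0.0)
        chrom_fits[c] = fit
    domain_fits = []
    for _, row in tads.domains().iterrows():
        a, b = int(row["start_bin"]), int(row["end_bin"])
        fit = _power_law_fit(dense[a:b, a:b])
        if fit is None:
            logger.info("domain %d-%d too small for its own fit; background used",
                        a, b)
            continue
        domain_fits.append((a, b, fit[0], fit[1]))
    return DomainBackground(g, domain_fits, chrom_fits)


@dataclass
class PEISet:
    """Called promoter-anchored interactions plus the full test table."""

    genome: BinnedGenome
    table: pd.DataFrame  # called PEIs
    n_tests: int
    fdr_threshold: float
    min_distance: int

    def __post_init__(self):
        t = self.table
        if len(t):
            assert (t["q"] < self.fdr_threshold).all()
            assert (t["distance"] >= self.min_distance).all()
            assert (t["observed"] > t["expected"]).all()


def call_peis(
    matrix: ContactMatrix,
    promoters: pd.DataFrame,
    background: DomainBackground,
    fdr_threshold: float = 0.01,
    min_distance: int = 15_000,
    max_span: int = 2_000_000,
    chunk_bp: int = 20_000_000,
    step_bp: int = 10_000_000,
) -> PEISet:
    """Call significant promoter-bin interactions.

    For each promoter bin, every bin within ``max_span`` on the same
    chromosome is tested: p = P(Poisson(expected) >= observed), BH-adjusted
    across all tests; kept when q < ``fdr_threshold``, genomic distance >=
    ``min_distance`` and observed > expected. Promoters are processed in
    overlapping genomic chunks (``chunk_bp`` wide, ``step_bp`` apart) purely
    for memory locality; every promoter is tested exactly once so results
    are invariant to the chunking.
    """
    g = matrix.genome
    dense = matrix.toarray()
    span_bins = max_span // g.bin_size
    records = []
    for chrom in g.chroms:
        s = g.chrom_slice(chrom)
        sub = promoters[promoters["chrom"] == chrom]
        if len(sub) == 0:
            continue
        length = g.chrom_sizes[chrom]
        seen = set()
        starts = range(0, max(1, length), step_bp)
        for w0 in starts:
            w1 = min(w0 + chunk_bp, length)
            for _, pr in sub.iterrows():
                if pr["gene"] in seen or not (w0 <= pr["tss"] < w1):
                    continue
                seen.add(pr["gene"])
                for pb in pr["bins"]:
                    lo = max(s.start, pb - span_bins)
                    hi = min(s.stop, pb + span_bins + 1)
                    js = np.arange(lo, hi)
                    js = js[js != pb]
                    if len(js) == 0:
                        continue
                    exp = background.expected_vector(pb, js)
                    ok = np.isfinite(exp) & (exp > 0)
                    js, exp = js[ok], exp[ok]
                    obs = dense[pb, js].astype(float)
                    p = poisson.sf(np.round(obs).astype(int) - 1, exp)
                    dist = np.abs(js - pb) * g.bin_size
                    records.extend(
                        zip(
                            [pr["gene"]] * len(js), [pb] * len(js),
                            js.tolist(), dist.tolist(), obs.tolist(),
                            exp.tolist(), p.tolist(),
                        )
                    )
            if w1 >= length:
                break
    if not records:
        logger.warning("no promoter tests performed")
        return PEISet(g, _empty_pei_table(), 0, fdr_threshold, min_distance)
    tests = pd.DataFrame(
        records,
        columns=["gene", "promoter_bin", "enhancer_bin", "distance",
                 "observed", "expected", "p"],
    )
    _, q, _, _ = multipletests(tests["p"].to_numpy(), method="fdr_bh")
    tests["q"] = q
    called = tests[
        (tests["q"] < fdr_threshold)
        & (tests["distance"] >= min_distance)
        & (tests["observed"] > tests["expected"])
    ].reset_index(drop=True)
    called = called.sort_values(
        ["gene", "promoter_bin", "enhancer_bin"]
    ).reset_index(drop=True)
    return PEISet(g, called, len(tests), fdr_threshold, min_distance)


def _empty_pei_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene", "promoter_bin", "enhancer_bin", "distance",
                 "observed", "expected", "p", "q"]
    )


@dataclass
class PEIStats:
    total: int
    genes_with_pei: int
    frac_short_range: float  # distance <= 100 kb
    frac_within_tad: float
    frac_skipping: float  # enhancer's nearest promoter is not its partner
    per_gene_counts: pd.Series


def pei_stats(peis: PEISet, tads: TADSet, promoters: pd.DataFrame) -> PEIStats:
    """Summary statistics of a called PEI set."""
    t = peis.table
    if len(t) == 0:
        raise ValueError("empty PEI set")
    g = peis.genome
    short = (t["distance"] <= 100_000).mean()

    domains = tads.domains()
    da = domains["start_bin"].to_numpy()
    db = domains["end_bin"].to_numpy()
    pb = t["promoter_bin"].to_numpy()
    eb = t["enhancer_bin"].to_numpy()
    lo = np.minimum(pb, eb)
    hi = np.maximum(pb, eb)
    within = (
        ((da[None, :] <= lo[:, None]) & (hi[:, None] < db[None, :])).any(axis=1)
        if len(domains)
        else np.zeros(len(t), dtype=bool)
    )

    # nearest promoter (by TSS distance) of each enhancer bin
    skip = np.zeros(len(t), dtype=bool)
    prom_by_chrom = {
        c: promoters[promoters["chrom"] == c] for c in g.chroms
    }
    for k, (_, row) in enumerate(t.iterrows()):
        chrom, start, end = g.bin_location(int(row["enhancer_bin"]))
        center = (start + end) // 2
        cands = prom_by_chrom.get(chrom)
        if cands is None or len(cands) == 0:
            continue
        d = np.abs(cands["tss"].to_numpy() - center)
        nearest_gene = cands.iloc[int(np.argmin(d))]["gene"]
        skip[k] = nearest_gene != row["gene"]

    counts = t.groupby("gene").size().sort_index()
    return PEIStats(
        total=len(t),
        genes_with_pei=t["gene"].nunique(),
        frac_short_range=float(short),
        frac_within_tad=float(within.mean()),
        frac_skipping=float(skip.mean()),
        per_gene_counts=counts,
    )


def compare_pei_sets(peis_1: PEISet, peis_2: PEISet, k: int = 10
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-gene PEI count change (stage2 - stage1) with top-k movers.

    Returns (delta table, top-k losers, top-k gainers); ordering is
    deterministic with ties broken by gene ID.
    """
    c1 = peis_1.table.groupby("gene").size()
    c2 = peis_2.table.groupby("gene").size()
    genes = sorted(set(c1.index) | set(c2.index))
    delta = pd.DataFrame(
        {
            "gene": genes,
            "n_stage1": [int(c1.get(g, 0)) for g in genes],
            "n_stage2": [int(c2.get(g, 0)) for g in genes],
        }
    )
    delta["delta"] = delta["n_stage2"] - delta["n_stage1"]
    if k > len(genes):
        logger.info("top-k truncated from %d to %d genes", k, len(genes))
        k = len(genes)
    losers = delta.sort_values(["delta", "gene"]).head(k).reset_index(drop=True)
    gainers = (
        delta.sort_values(["delta", "gene"], ascending=[False, True])
        .head(k)
        .reset_index(drop=True)
    )
    return delta, losers, gainers


def write_bedpe(peis: PEISet, path) -> None:
    """Called PEIs as BEDPE plus gene/statistics columns."""
    g = peis.genome
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tgene\tobserved\t"
            "expected\tp\tq\tdistance\n"
        )
        for _, r in peis.table.iterrows():
            c1, s1, e1 = g.bin_location(int(r["promoter_bin"]))
            c2, s2, e2 = g.bin_location(int(r["enhancer_bin"]))
            fh.write(
                f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\t{r['gene']}\t"
                f"{r['observed']:.6g}\t{r['expected']:.6g}\t{r['p']:.6g}\t"
                f"{r['q']:.6g}\t{int(r['distance'])}\n"
            )
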