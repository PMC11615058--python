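"""TAD calling and comparison.

Two complementary boundary signals are computed from a balanced contact
matrix: the directionality index (DI), a chi-square-like statistic
contrasting upstream vs downstream contact sums in a sliding window,
segmented by a 3-state Gaussian HMM (downstream-biased / none /
upstream-biased); and the insulation score (IS), the log2 ratio of
contacts crossing a bin to the chromosome average, whose local minima mark
boundaries. Domains, boundaries and unorganized stretches are combined
into a TADSet; each domain gets a D-score (fraction of its contact mass
that is intra-domain) and a compartment label (A/B when >70% of its bins
share one compartment). Two stages are compared by boundary Jaccard,
DI Spearman correlation, and a standardized delta-IS boundary score
(threshold 1.5 by default) that flags differential boundaries and TADs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy.signal import find_peaks
from scipy.stats import spearmanr

from .compartments import CompartmentProfile
from .genome import BinnedGenome
from .matrix import ContactMatrix

logger = logging.getLogger(__name__)

DOWNSTREAM, NONE, UPSTREAM = 1, 0, -1  # HMM state codes (sign of DI bias)


@dataclass
class DITrack:
    genome: BinnedGenome
    values: np.ndarray
    window_bp: int


@dataclass
class ISTrack:
    genome: BinnedGenome
    values: np.ndarray  # log2 vs chromosome mean; NaN where window unfit
    window_bp: int
    boundaries: np.ndarray  # global bin indices of IS minima


@dataclass
class HMMResult:
    genome: BinnedGenome
    states: np.ndarray  # per-bin in {-1, 0, +1}
    domains: list  # list of (start_bin, end_bin) global, half-open


@dataclass
class TADSet:
    """Non-overlapping classified intervals (domain/boundary/unorganized)."""

    genome: BinnedGenome
    table: pd.DataFrame  # chrom,start,end,start_bin,end_bin,class,dscore,compartment

    def __post_init__(self):
        t = self.table.sort_values(["start_bin"]).reset_index(drop=True)
        if len(t) > 1:
            overlap = t["start_bin"].to_numpy()[1:] < t["end_bin"].to_numpy()[:-1]
            if overlap.any():
                raise ValueError("TADSet intervals overlap")
        self.table = t

    def domains(self) -> pd.DataFrame:
        return self.table[self.table["class"] == "domain"].reset_index(drop=True)

    def boundary_bins(self) -> np.ndarray:
        """Sorted unique domain-edge bins (starts and ends)."""
        d = self.domains()
        edges = np.concatenate([d["start_bin"].to_numpy(), d["end_bin"].to_numpy()])
        return np.unique(edges)


@dataclass
class TADComparison:
    jaccard: float
    spearman_di: float
    shared_boundaries: np.ndarray
    specific_1: np.ndarray
    specific_2: np.ndarray
    consensus_boundaries: np.ndarray
    boundary_scores: pd.DataFrame  # boundary_bin, delta_is, zscore, differential
    differential_boundaries: np.ndarray
    differential_tads: pd.DataFrame


# ------------------------------------------------------------------ tracks
def directionality_index(matrix: ContactMatrix, window_bp: int = 1_000_000
                         ) -> DITrack:
    """Directionality index per bin.

    With A (B) the contact sum from bin i to the ``window_bp`` of upstream
    (downstream) bins and E = (A+B)/2::

        DI = sign(B - A) * [(A-E)^2/E + (B-E)^2/E]

    0 where A == B or both windows are empty. Windows are truncated at
    chromosome edges.
    """
    g = matrix.genome
    w = window_bp // g.bin_size
    if w < 2:
        raise ValueError("DI window must cover >= 2 bins")
    dense = matrix.toarray().astype(float)
    di = np.zeros(g.n_bins)
    for c in g.chroms:
        n = g.n_bins_of(c)
        if w > n:
            raise ValueError(f"DI window larger than chromosome {c}")
        s = g.chrom_slice(c)
        block = dense[s, s]
        for i in range(n):
            a = block[i, max(0, i - w): i].sum()
            b = block[i, i + 1: i + 1 + w].sum()
            e = (a + b) / 2.0
            if e == 0 or a == b:
                continue
            di[s.start + i] = np.sign(b - a) * (
                (a - e) ** 2 / e + (b - e) ** 2 / e
            )
    return DITrack(g, di, window_bp)


def fit_hmm(di: DITrack, max_iter: int = 100, seed: int = 0,
            refine_window: int = 5) -> HMMResult:
    """Segment the DI track with a 3-state Gaussian HMM.

    The DI is winsorized (0.5th/99.5th percentiles, taming chromosome-edge
    outliers) and standardized, so segmentation is invariant to the matrix
    scale. Emission means start on the tail deciles (low / zero / high)
    with per-group variances; EM then refines, and states are identified by
    the order of their fitted means (lowest = upstream-biased, highest =
    downstream-biased), making output stable across seeds on separable
    input. A domain spans from the start of a downstream-biased run to the
    end of the following upstream-biased run; each edge is then refined to
    the DI extremum within ``refine_window`` bins (ties resolved toward the
    HMM edge), where the up/downstream bias physically peaks.
    """
    v = di.values
    if not np.all(np.isfinite(v)):
        raise ValueError("DI track must be finite")
    g = di.genome
    if np.std(v) == 0:
        return HMMResult(g, np.zeros(g.n_bins, dtype=int), [])
    lo, hi = np.quantile(v, [0.005, 0.995])
    z = np.clip(v, lo, hi)
    z = z / z.std()
    x = z.reshape(-1, 1)
    lengths = [g.n_bins_of(c) for c in g.chroms]
    q10, q90 = np.quantile(z, [0.10, 0.90])
    groups = [z[z <= q10], z[(z > q10) & (z < q90)], z[z >= q90]]
    model = GaussianHMM(
        n_components=3,
        covariance_type="diag",
        n_iter=max_iter,
        init_params="",
        params="stmc",
        random_state=seed,
    )
    model.startprob_ = np.full(3, 1 / 3)
    model.transmat_ = np.full((3, 3), 0.05) + np.eye(3) * 0.85
    model.means_ = np.array([[grp.mean() if len(grp) else 0.0] for grp in groups])
    model.covars_ = np.array(
        [[max(grp.var(), 1e-6) if len(grp) else 1e-6] for grp in groups]
    )
    model.fit(x, lengths)
    if not model.monitor_.converged:
        raise RuntimeError(
            "HMM EM did not converge; last log-likelihood "
            f"{model.monitor_.history[-1]:.6g}"
        )
    raw_states = model.predict(x, lengths)
    order = np.argsort(model.means_.ravel())
    remap = np.empty(3, dtype=int)
    remap[order] = [UPSTREAM, NONE, DOWNSTREAM]
    states = remap[raw_states]

    domains = []
    for c in g.chroms:
        s = g.chrom_slice(c)
        refined = [
            _refine_edges(v, a, b, s.start, s.stop, refine_window)
            for a, b in _segment_domains(states[s], offset=s.start)
        ]
        # refinement may nudge adjacent edges past each other; re-impose
        # non-overlap by clipping at the previous domain's end
        prev_end = s.start
        for a, b in refined:
            a = max(a, prev_end)
            if b - a >= 2:
                domains.append((a, b))
                prev_end = b
    return HMMResult(g, states, domains)


def _extremum_near(v: np.ndarray, center: int, lo: int, hi: int, k: int,
                   mode: str) -> int:
    """Index of the DI max/min within [center-k, center+k] (clipped to
    [lo, hi)); exact ties go to the index nearest ``center``."""
    a = max(lo, center - k)
    b = min(hi, center + k + 1)
    window = v[a:b]
    target = window.max() if mode == "max" else window.min()
    idx = np.flatnonzero(window == target) + a
    return int(idx[np.argmin(np.abs(idx - center))])


def _refine_edges(v: np.ndarray, a: int, b: int, lo: int, hi: int, k: int
                  ) -> tuple[int, int]:
    a2 = _extremum_near(v, a, lo, hi, k, "max")
    b2 = _extremum_near(v, b - 1, lo, hi, k, "min") + 1
    if b2 - a2 >= 2:
        return a2, b2
    return a, b


def _segment_domains(states: np.ndarray, offset: int = 0) -> list:
    """Domains: downstream-biased run start -> end of next upstream run."""
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((int(states[start]), start, i))
            start = i
    domains = []
    open_start = None
    last_neg_end = None
    for val, s, e in runs:
        if val == DOWNSTREAM:
            if open_start is not None and last_neg_end is not None:
                domains.append((offset + open_start, offset + last_neg_end))
                open_start, last_neg_end = s, None
            elif open_start is None:
                open_start = s
        elif val == UPSTREAM and open_start is not None:
            last_neg_end = e
    if open_start is not None and last_neg_end is not None:
        domains.append((offset + open_start, offset + last_neg_end))
    return domains


def insulation_score(
    matrix: ContactMatrix, window_bp: int = 500_000, min_prominence: float = 0.1
) -> ISTrack:
    """Insulation score: log2 of cross-bin contact flux vs chromosome mean.

    For each bin i the mean contact count in the w x w square spanning
    [i-w, i) x (i, i+w] is taken; IS(i) = log2(square / chromosome mean of
    squares). Defined only where the window fits inside the chromosome;
    boundaries are IS local minima with prominence >= ``min_prominence``.
    Invariant under global scaling of the matrix.
    """
    g = matrix.genome
    w = window_bp // g.bin_size
    if w < 1:
        raise ValueError("IS window must cover >= 1 bin")
    dense = matrix.toarray().astype(float)
    is_vals = np.full(g.n_bins, np.nan)
    boundaries = []
    for c in g.chroms:
        n = g.n_bins_of(c)
        s = g.chrom_slice(c)
        block = dense[s, s]
        if n < 2 * w + 1:
            continue
        sq = np.full(n, np.nan)
        for i in range(w, n - w):
            sq[i] = block[i - w: i, i + 1: i + 1 + w].mean()
        defined = np.isfinite(sq) & (sq > 0)
        if not defined.any():
            continue
        mean = sq[defined].mean()
        vals = np.full(n, np.nan)
        vals[defined] = np.log2(sq[defined] / mean)
        is_vals[s] = vals
        # peak search restricted to the defined window so the NaN flanks
        # cannot manufacture plateau minima
        lo, hi = w, n - w
        seg = vals[lo:hi].copy()
        if np.isnan(seg).any():
            seg[np.isnan(seg)] = np.nanmax(seg) if np.isfinite(seg).any() else 0.0
        peaks, _ = find_peaks(-seg, prominence=min_prominence)
        boundaries.extend((s.start + lo + p) for p in peaks)
    return ISTrack(g, is_vals, window_bp, np.asarray(sorted(boundaries), dtype=int))


# ------------------------------------------------------------------ calling
def call_tads(
    hmm: HMMResult,
    is_track: ISTrack,
    min_gap: int = 3,
    match_tol: int = 1,
) -> TADSet:
    """Combine HMM segmentation and IS minima into a classified TADSet.

    Domains come from the HMM segmentation; a boundary bin is an IS local
    minimum lying within ``match_tol`` bins of a domain edge (and outside
    any domain); runs of 'none'-state bins longer than ``min_gap`` outside
    domains are unorganized. Output intervals never overlap.
    """
    g = hmm.genome
    if not g.same_partition(is_track.genome):
        raise ValueError("DI/HMM and IS tracks must share one partition")
    in_domain = np.zeros(g.n_bins, dtype=bool)
    rows = []
    for a, b in hmm.domains:
        in_domain[a:b] = True
        chrom, start, _ = g.bin_location(a)
        _, _, end = g.bin_location(b - 1)
        rows.append((chrom, start, end, a, b, "domain"))
    edges = (
        np.unique(np.concatenate([np.array(hmm.domains).ravel()]))
        if hmm.domains
        else np.array([], dtype=int)
    )
    for m in is_track.boundaries:
        if len(edges) and np.min(np.abs(edges - m)) <= match_tol and not in_domain[m]:
            chrom, start, end = g.bin_location(int(m))
            rows.append((chrom, start, end, int(m), int(m) + 1, "boundary"))
            in_domain[m] = True  # reserve the bin
    none_state = hmm.states == NONE
    for c in g.chroms:
        s = g.chrom_slice(c)
        free = none_state[s] & ~in_domain[s]
        start = None
        for i in range(len(free) + 1):
            if i < len(free) and free[i]:
                start = i if start is None else start
            else:
                if start is not None and i - start > min_gap:
                    a, b = s.start + start, s.start + i
                    chrom, st, _ = g.bin_location(a)
                    _, _, en = g.bin_location(b - 1)
                    rows.append((chrom, st, en, a, b, "unorganized"))
                start = None
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "start_bin", "end_bin", "class"],
    )
    table["dscore"] = np.nan
    table["compartment"] = ""
    return TADSet(g, table)


def domain_score(matrix: ContactMatrix, tads: TADSet) -> pd.Series:
    """Per-domain D-score: intra-domain contacts / contacts touching the domain.

    Both sums count each contact once (upper triangle); D is in (0, 1],
    NaN (flagged) for domains with zero contact mass.
    """
    upper = np.triu(matrix.toarray().astype(float))
    g = matrix.genome
    scores = []
    for _, row in tads.table.iterrows():
        if row["class"] != "domain":
            scores.append(np.nan)
            continue
        a, b = int(row["start_bin"]), int(row["end_bin"])
        if b > g.n_bins:
            raise ValueError("TAD outside matrix bounds")
        intra = upper[a:b, a:b].sum()
        touching = upper[a:b, :].sum() + upper[:, a:b].sum() - intra
        if touching == 0:
            logger.warning("domain %d-%d has zero contacts; D-score undefined",
                           a, b)
            scores.append(np.nan)
        else:
            scores.append(intra / touching)
    tads.table["dscore"] = scores
    return pd.Series(scores, index=tads.table.index, name="dscore")


def tad_compartment_label(tads: TADSet, profile: CompartmentProfile) -> pd.Series:
    """Label a TAD A (B) when >70% of its labeled bins are A (B), else mixed."""
    labels = []
    for _, row in tads.table.iterrows():
        a, b = int(row["start_bin"]), int(row["end_bin"])
        lab = profile.labels[a:b]
        lab = lab[lab != "excluded"]
        if len(lab) == 0:
            logger.warning("TAD %d-%d has no labeled bins", a, b)
            labels.append("undefined")
            continue
        frac_a = np.mean(lab == "A")
        if frac_a > 0.7:
            labels.append("A")
        elif (1 - frac_a) > 0.7:
            labels.append("B")
        else:
            labels.append("mixed")
    tads.table["compartment"] = labels
    return pd.Series(labels, index=tads.table.index, name="compartment")


# --------------------------------------------------------------- comparison
def _match_boundaries(b1: np.ndarray, b2: np.ndarray, tol: int
                      ) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    """Greedy one-to-one matching within +-tol bins."""
    used2 = np.zeros(len(b2), dtype=bool)
    shared = []
    spec1 = []
    for x in b1:
        d = np.abs(b2 - x)
        d[used2] = tol + 1
        if len(b2) and d.min() <= tol:
            j = int(np.argmin(d))
            used2[j] = True
            shared.append(x)
        else:
            spec1.append(x)
    spec2 = b2[~used2]
    return len(shared), np.asarray(shared), np.asarray(spec1), np.asarray(spec2)


def compare_tads(
    tads_1: TADSet,
    tads_2: TADSet,
    di_1: DITrack,
    di_2: DITrack,
    is_1: ISTrack,
    is_2: ISTrack,
    match_tol_bins: int = 1,
    boundary_score_threshold: float = 1.5,
) -> TADComparison:
    """Compare two stage TADSets.

    Boundaries are matched one-to-one within ``match_tol_bins``; Jaccard =
    matched / union. The DI tracks are compared by Spearman correlation.
    Each consensus boundary gets a boundary score: the z-score of its
    IS change (stage2 - stage1) against the genome-wide delta-IS
    distribution; boundaries with |z| > ``boundary_score_threshold``
    (default 1.5) are differential, and domains whose edge sits within the
    tolerance of a differential boundary are differential TADs.
    """
    b1 = tads_1.boundary_bins()
    b2 = tads_2.boundary_bins()
    if len(b1) == 0 or len(b2) == 0:
        raise ValueError("cannot compare: a stage has no TAD boundaries")
    m, shared, spec1, spec2 = _match_boundaries(b1, b2, match_tol_bins)
    jaccard = m / (len(b1) + len(b2) - m)

    ok = np.isfinite(di_1.values) & np.isfinite(di_2.values)
    rho = float(spearmanr(di_1.values[ok], di_2.values[ok]).statistic)

    # consensus boundaries: union merged within tolerance (cluster means)
    allb = np.sort(np.concatenate([b1, b2]))
    consensus = []
    cluster = [allb[0]]
    for x in allb[1:]:
        if x - cluster[-1] <= match_tol_bins:
            cluster.append(x)
        else:
            consensus.append(int(round(np.mean(cluster))))
            cluster = [x]
    consensus.append(int(round(np.mean(cluster))))
    consensus = np.asarray(consensus)

    delta = is_2.values - is_1.values
    ok_d = np.isfinite(delta)
    mu, sd = delta[ok_d].mean(), delta[ok_d].std()
    rows = []
    for b in consensus:
        # a domain ending at the chromosome edge has its boundary at n_bins
        bi = min(int(b), len(delta) - 1)
        d_at = delta[bi] if ok_d[bi] else np.nan
        z = (d_at - mu) / sd if sd > 0 and np.isfinite(d_at) else np.nan
        rows.append(
            {
                "boundary_bin": int(b),
                "delta_is": d_at,
                "zscore": z,
                "differential": bool(
                    np.isfinite(z) and abs(z) > boundary_score_threshold
                ),
            }
        )
    scores = pd.DataFrame(rows)
    diff_b = scores.loc[scores["differential"], "boundary_bin"].to_numpy()

    diff_tads = []
    for name, ts in (("stage1", tads_1), ("stage2", tads_2)):
        for _, row in ts.domains().iterrows():
            edges = np.array([row["start_bin"], row["end_bin"]])
            if len(diff_b) and np.min(
                np.abs(diff_b[:, None] - edges[None, :])
            ) <= match_tol_bins:
                diff_tads.append(
                    {
                        "stage": name,
                        "chrom": row["chrom"],
                        "start": row["start"],
                        "end": row["end"],
                        "start_bin": row["start_bin"],
                        "end_bin": row["end_bin"],
                    }
                )
    return TADComparison(
        jaccard=jaccard,
        spearman_di=rho,
        shared_boundaries=shared,
        specific_1=spec1,
        specific_2=spec2,
        consensus_boundaries=consensus,
        boundary_scores=scores,
        differential_boundaries=diff_b,
        differential_tads=pd.DataFrame(diff_tads),
    )


# --------------------------------------------------------------- enrichment
def boundary_gene_enrichment(
    boundary_bins: np.ndarray,
    genes: pd.DataFrame,
    genome: BinnedGenome,
    flank_bp: int = 500_000,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Gene enrichment around boundaries vs circular-permutation null.

    Counts genes whose TSS lies within +-``flank_bp`` of a boundary and
    compares with the mean count over ``n_perm`` circular shifts of the
    boundary positions along each chromosome. Returns (ratio, empirical p).
    """
    boundary_bins = np.asarray(boundary_bins, dtype=int)
    if len(boundary_bins) < 2:
        raise ValueError("need >= 2 boundaries for enrichment")
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    tss_col = "tss" if "tss" in genes.columns else "start"
    by_chrom = {}
    for c in genome.chroms:
        s = genome.chrom_slice(c)
        local = boundary_bins[(boundary_bins >= s.start) & (boundary_bins < s.stop)]
        by_chrom[c] = local - s.start
    gene_pos = {
        c: genes.loc[genes["chrom"] == c, tss_col].to_numpy()
        for c in genome.chroms
    }

    def count(shifted: dict) -> int:
        total = 0
        for c, locs in shifted.items():
            if len(locs) == 0 or len(gene_pos[c]) == 0:
                continue
            centers = locs * genome.bin_size + genome.bin_size // 2
            d = np.abs(gene_pos[c][:, None] - centers[None, :])
            total += int(np.sum(d.min(axis=1) <= flank_bp))
        return total

    observed = count(by_chrom)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        shifted = {}
        for c, locs in by_chrom.items():
            n = genome.n_bins_of(c)
            shifted[c] = (locs + int(rng.integers(n))) % n if len(locs) else locs
        null[k] = count(shifted)
    ratio = observed / null.mean() if null.mean() > 0 else np.inf
    p = (1 + np.sum(null >= observed)) / (n_perm + 1)
    return float(ratio), float(p)
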