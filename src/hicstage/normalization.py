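"""Matrix balancing and between-sample normalization.

ICE (iterative correction) and KR-style balancing both remove
multiplicative per-bin coverage bias by finding a diagonal scaling of the
contact matrix; ICE targets equal marginals at roughly the original scale,
the KR routine targets a doubly stochastic matrix (row sums 1). Between
samples, a per-distance-stratum quantile normalization equalizes the
intra-chromosomal count distributions. Reproducibility between maps is
scored with a stratum-adjusted correlation coefficient (SCC): a
variance- and size-weighted sum of per-distance Pearson correlations on
mean-filter-smoothed matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.sparse.csgraph import connected_components

from .matrix import ContactMatrix

logger = logging.getLogger(__name__)

LOW_COVERAGE_PERCENTILE = 2.0  # mask bins below this %ile of nonzero marginals


@dataclass
class BiasVector:
    """Per-bin positive multiplicative bias; NaN on excluded bins."""

    values: np.ndarray
    excluded: np.ndarray

    def __post_init__(self):
        inc = ~self.excluded
        if not np.all(np.isfinite(self.values[inc])) or np.any(
            self.values[inc] <= 0
        ):
            raise ValueError("bias must be finite and positive on included bins")


@dataclass
class SCCResult:
    """Stratum-adjusted correlation: per-stratum r, weights, weighted sum."""

    distances: np.ndarray
    correlations: np.ndarray
    weights: np.ndarray  # sum to 1 over used strata
    scc: float


def balancing_mask(dense: np.ndarray, extra_excluded: np.ndarray = None
                   ) -> np.ndarray:
    """Included-bin mask: drops zero-marginal bins, the lowest-coverage
    bins (below the 2nd percentile of nonzero marginals), and any
    externally excluded bins."""
    marg = dense.sum(axis=1)
    include = marg > 0
    if include.any():
        cutoff = np.percentile(marg[include], LOW_COVERAGE_PERCENTILE)
        include &= marg >= cutoff
    if extra_excluded is not None:
        include &= ~extra_excluded
    return include


def ice_normalize(
    matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-5
) -> tuple[ContactMatrix, BiasVector]:
    """Iterative correction: equalize included-bin marginals.

    Iterates ``W <- W / (s s^T)`` with ``s`` the mean-normalized marginal
    vector until the coefficient of variation of marginals drops below
    ``tol``. The original matrix is recoverable as ``W_ij * b_i * b_j`` up
    to a global scale.
    """
    dense = matrix.toarray().astype(float)
    if dense.sum() == 0:
        raise ValueError("cannot balance an all-zero matrix")
    include = balancing_mask(dense, matrix.genome.excluded)
    sub = dense[np.ix_(include, include)].copy()
    bias_sub = np.ones(sub.shape[0])
    cv = np.inf
    for _ in range(max_iter):
        marg = sub.sum(axis=1)
        mean = marg.mean()
        if mean == 0:
            raise ValueError("included submatrix has zero total")
        cv = marg.std() / mean
        if cv < tol:
            break
        s = marg / mean
        sub /= np.outer(s, s)
        bias_sub *= s
    else:
        warnings.warn(
            f"ICE did not reach tol={tol} in {max_iter} iterations "
            f"(achieved CV {cv:.3g})"
        )

    out = np.zeros_like(dense)
    out[np.ix_(include, include)] = sub
    bias = np.full(dense.shape[0], np.nan)
    bias[include] = bias_sub
    balanced = ContactMatrix.from_dense(matrix.genome, out, raw=False)
    return balanced, BiasVector(bias, ~include)


def kr_normalize(
    matrix: ContactMatrix, tol: float = 1e-8, max_iter: int = 3000
) -> tuple[ContactMatrix, BiasVector]:
    """Balance to a doubly stochastic matrix (row sums 1 on included bins).

    Finds the positive diagonal ``x`` with ``x_i (A x)_i = 1`` via the
    damped symmetric fixed point ``x <- sqrt(x / (A x))``, the unique
    scaling a Knight-Ruiz solver converges to on symmetric irreducible
    input.
    """
    dense = matrix.toarray().astype(float)
    if dense.sum() == 0:
        raise ValueError("cannot balance an all-zero matrix")
    include = balancing_mask(dense, matrix.genome.excluded)
    sub = dense[np.ix_(include, include)]
    _check_irreducible(sub)
    x = 1.0 / np.sqrt(sub.sum(axis=1))
    for _ in range(max_iter):
        ax = sub @ x
        x = np.sqrt(x / ax)
        err = np.max(np.abs(x * (sub @ x) - 1.0))
        if err <= tol:
            break
    else:
        warnings.warn(
            f"KR balancing did not reach tol={tol} in {max_iter} iterations "
            f"(max |rowsum-1| = {err:.3g})"
        )
    balanced_sub = sub * np.outer(x, x)

    out = np.zeros_like(dense)
    out[np.ix_(include, include)] = balanced_sub
    bias = np.full(dense.shape[0], np.nan)
    bias[include] = 1.0 / x  # original ~ out * b_i * b_j
    balanced = ContactMatrix.from_dense(matrix.genome, out, raw=False)
    return balanced, BiasVector(bias, ~include)


def _check_irreducible(sub: np.ndarray) -> None:
    zero_rows = np.flatnonzero(sub.sum(axis=1) == 0)
    if len(zero_rows):
        raise ValueError(
            f"matrix has zero rows after exclusion at included indices "
            f"{zero_rows.tolist()[:10]}"
        )
    n_comp, labels = connected_components(sub > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"matrix is reducible: {n_comp} connected components of sizes "
            f"{sizes.tolist()}"
        )


def write_bias(bias: BiasVector, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin\tbias\n")
        for i, v in enumerate(bias.values):
            fh.write(f"{i}\t{'NA' if np.isnan(v) else f'{v:.10g}'}\n")


# ------------------------------------------------------------- quantile
def _intra_distance_entries(dense: np.ndarray, genome, d: int) -> np.ndarray:
    parts = []
    for c in genome.chroms:
        s = genome.chrom_slice(c)
        block = dense[s, s]
        if d < block.shape[0]:
            parts.append(np.diagonal(block, offset=d))
    if not parts:
        return np.array([])
    return np.concatenate(parts)


def quantile_normalize(samples: list[ContactMatrix]) -> list[ContactMatrix]:
    """Per-distance-stratum quantile normalization across samples.

    Within each intra-chromosomal bin distance, entries of every sample are
    replaced by the rank-wise mean of the samples' sorted values (ties are
    broken by genomic position, deterministically), making the per-stratum
    distributions exactly identical across samples. Inter-chromosomal
    entries are left untouched.
    """
    if len(samples) < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    g0 = samples[0].genome
    for s in samples[1:]:
        if not g0.same_partition(s.genome):
            raise ValueError("samples must share one genome partition")
    denses = [s.toarray().astype(float) for s in samples]
    max_bins = max(g0.n_bins_of(c) for c in g0.chroms)
    for d in range(1, max_bins):
        cols = [_intra_distance_entries(m, g0, d) for m in denses]
        if cols[0].size == 0:
            break
        sorted_mean = np.mean([np.sort(v) for v in cols], axis=0)
        for m, v in zip(denses, cols):
            # rank-wise assignment (ties broken by position, deterministic):
            # every sample ends up with the identical per-stratum multiset
            new = np.empty_like(v)
            order = np.argsort(v, kind="stable")
            new[order] = sorted_mean
            _set_intra_distance_entries(m, g0, d, new)
    out = []
    for m in denses:
        out.append(ContactMatrix.from_dense(g0, m, raw=False))
    return out


def _set_intra_distance_entries(dense: np.ndarray, genome, d: int,
                                values: np.ndarray) -> None:
    pos = 0
    for c in genome.chroms:
        s = genome.chrom_slice(c)
        n = genome.n_bins_of(c)
        if d >= n:
            continue
        k = n - d
        idx = np.arange(k)
        dense[s.start + idx, s.start + idx + d] = values[pos: pos + k]
        dense[s.start + idx + d, s.start + idx] = values[pos: pos + k]
        pos += k


# ------------------------------------------------------------------ SCC
def scc_reproducibility(
    m1: ContactMatrix,
    m2: ContactMatrix,
    smooth_span: int = 2,
    max_distance: int = 5_000_000,
) -> SCCResult:
    """Stratum-adjusted correlation coefficient between two maps.

    Both intra-chromosomal matrices are smoothed with a (2h+1)-wide 2D mean
    filter; for each bin distance d <= max_distance a Pearson correlation
    is computed over all chromosomes, weighted by stratum size times the
    geometric mean of the two stratum standard deviations. Zero-variance
    strata are skipped with weight 0.
    """
    g = m1.genome
    if not g.same_partition(m2.genome):
        raise ValueError("matrices must share one genome partition")
    size = 2 * smooth_span + 1
    sm1, sm2 = {}, {}
    for c in g.chroms:
        s = g.chrom_slice(c)
        sm1[c] = uniform_filter(m1.toarray()[s, s].astype(float), size=size,
                                mode="nearest")
        sm2[c] = uniform_filter(m2.toarray()[s, s].astype(float), size=size,
                                mode="nearest")
    max_d = max(1, max_distance // g.bin_size)
    dists, corrs, raw_w = [], [], []
    for d in range(1, max_d + 1):
        x_parts, y_parts = [], []
        for c in g.chroms:
            n = g.n_bins_of(c)
            if d < n:
                x_parts.append(np.diagonal(sm1[c], offset=d))
                y_parts.append(np.diagonal(sm2[c], offset=d))
        if not x_parts:
            break
        x = np.concatenate(x_parts)
        y = np.concatenate(y_parts)
        vx, vy = x.std(), y.std()
        if vx == 0 or vy == 0 or len(x) < 2:
            logger.debug("SCC: skipping degenerate stratum d=%d", d)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        dists.append(d)
        corrs.append(r)
        raw_w.append(len(x) * vx * vy)
    if not dists:
        raise ValueError("no usable distance strata for SCC")
    w = np.asarray(raw_w) / np.sum(raw_w)
    scc = float(np.sum(w * np.asarray(corrs)))
    return SCCResult(np.asarray(dists), np.asarray(corrs), w, scc)
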