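"""Two-condition Hi-C simulator with planted ground truth.

Generates contact maps whose statistical structure mirrors what the
downstream analyses assume: power-law distance decay, plaid (checkerboard)
compartment structure, block-diagonal TAD enrichment, focal
promoter-enhancer peaks, per-bin coverage bias, and Poisson counting noise;
plus gene annotations and expression tables coupled to compartment status.
Every planted feature is recorded in a :class:`TruthModel` so recovery can
be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .matrix import ContactMatrix

SWITCH_CLASSES = ("AA", "BB", "AB", "BA")  # AB = A->B, BA = B->A


@dataclass
class TruthModel:
    """Planted ground truth for one simulated Hi-C condition.

    Parameters
    ----------
    bin_size : int
        Bin width in bp.
    chrom_partition : list of (chrom, n_bins)
        Ordered genome partition; every chromosome is an integer number of
        full-width bins.
    compartment_labels : array of 'A'/'B'
        Per-bin planted compartment label (covers every bin).
    tads : list of (start_bin, end_bin, intra_enrichment)
        Planted domains in global bin coordinates, half-open, sorted,
        non-overlapping, each within one chromosome; enrichment >= 1.
    peis : list of (promoter_bin, enhancer_bin, fold_enrichment)
        Planted focal peaks; anchors differ, same chromosome, fold >= 1.
    decay_exponent : float
        Power-law exponent of intra-chromosomal distance decay (< 0).
    plaid_strength : float
        Same-compartment contact multiplier (>= 1); opposite-compartment
        pairs are divided by it.
    coverage_bias : array of float
        Strictly positive per-bin coverage multiplier.
    base_depth : float
        Expected intensity scale of an unbiased intra pair at unit bin
        distance; the matrix total is the sum of all pair intensities.
    inter_level : float
        Constant expected intensity of an unbiased inter-chromosomal pair.
    seed : int
        Seed recorded with the model (generation uses explicit seeds).
    """

    bin_size: int
    chrom_partition: list
    compartment_labels: np.ndarray
    tads: list = field(default_factory=list)
    peis: list = field(default_factory=list)
    decay_exponent: float = -1.0
    plaid_strength: float = 1.5
    coverage_bias: np.ndarray = None
    base_depth: float = 800.0
    inter_level: float = 13.0
    seed: int = 0

    def __post_init__(self):
        self.chrom_partition = [(str(c), int(n)) for c, n in self.chrom_partition]
        n = self.n_bins
        self.compartment_labels = np.asarray(self.compartment_labels, dtype="U1")
        if self.compartment_labels.shape != (n,):
            raise ValueError("compartment labels must cover every bin")
        if not set(np.unique(self.compartment_labels)) <= {"A", "B"}:
            raise ValueError("compartment labels must be 'A' or 'B'")
        if self.coverage_bias is None:
            self.coverage_bias = np.ones(n)
        self.coverage_bias = np.asarray(self.coverage_bias, dtype=float)
        if self.coverage_bias.shape != (n,) or np.any(self.coverage_bias <= 0):
            raise ValueError("coverage_bias must be positive per bin")
        if self.decay_exponent >= 0:
            raise ValueError("decay_exponent must be negative")
        if self.plaid_strength < 1:
            raise ValueError("plaid_strength must be >= 1")
        self.tads = [(int(a), int(b), float(e)) for a, b, e in self.tads]
        self._validate_tads()
        self.peis = [(int(p), int(q), float(f)) for p, q, f in self.peis]
        self._validate_peis()

    # ------------------------------------------------------------ helpers
    @property
    def n_bins(self) -> int:
        return sum(n for _, n in self.chrom_partition)

    @property
    def genome(self) -> BinnedGenome:
        return BinnedGenome.from_partition(self.chrom_partition, self.bin_size)

    def chrom_bounds(self) -> list[tuple[int, int]]:
        """Global (start, end) bin bounds of each chromosome."""
        bounds, off = [], 0
        for _, n in self.chrom_partition:
            bounds.append((off, off + n))
            off += n
        return bounds

    def _chrom_of_bin(self, i: int) -> int:
        for k, (a, b) in enumerate(self.chrom_bounds()):
            if a <= i < b:
                return k
        raise IndexError(i)

    def _validate_tads(self):
        prev_end = -1
        bounds = self.chrom_bounds()
        for a, b, e in self.tads:
            if not (0 <= a < b <= self.n_bins):
                raise ValueError(f"TAD ({a},{b}) outside genome")
            if a < prev_end:
                raise ValueError("TADs must be sorted and non-overlapping")
            if e < 1:
                raise ValueError("TAD enrichment must be >= 1")
            if not any(ca <= a and b <= cb for ca, cb in bounds):
                raise ValueError(f"TAD ({a},{b}) crosses a chromosome bound")
            prev_end = b

    def _validate_peis(self):
        for p, q, f in self.peis:
            if p == q:
                raise ValueError("PEI anchors must differ")
            if self._chrom_of_bin(p) != self._chrom_of_bin(q):
                raise ValueError("PEI anchors must share a chromosome")
            if f < 1:
                raise ValueError("PEI fold enrichment must be >= 1")

    # ------------------------------------------------------------ IO
    def to_json(self, path: str | Path) -> None:
        obj = {
            "bin_size": self.bin_size,
            "chrom_partition": self.chrom_partition,
            "compartment_labels": "".join(self.compartment_labels),
            "tads": self.tads,
            "peis": self.peis,
            "decay_exponent": self.decay_exponent,
            "plaid_strength": self.plaid_strength,
            "coverage_bias": self.coverage_bias.tolist(),
            "base_depth": self.base_depth,
            "inter_level": self.inter_level,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            bin_size=int(obj["bin_size"]),
            chrom_partition=[tuple(x) for x in obj["chrom_partition"]],
            compartment_labels=np.array(list(obj["compartment_labels"])),
            tads=[tuple(x) for x in obj["tads"]],
            peis=[tuple(x) for x in obj["peis"]],
            decay_exponent=obj["decay_exponent"],
            plaid_strength=obj["plaid_strength"],
            coverage_bias=np.asarray(obj["coverage_bias"]),
            base_depth=obj["base_depth"],
            inter_level=obj["inter_level"],
            seed=int(obj["seed"]),
        )

    def __eq__(self, other):
        if not isinstance(other, TruthModel):
            return NotImplemented
        return (
            self.bin_size == other.bin_size
            and self.chrom_partition == other.chrom_partition
            and np.array_equal(self.compartment_labels, other.compartment_labels)
            and self.tads == other.tads
            and self.peis == other.peis
            and self.decay_exponent == other.decay_exponent
            and self.plaid_strength == other.plaid_strength
            and np.allclose(self.coverage_bias, other.coverage_bias)
            and self.base_depth == other.base_depth
            and self.inter_level == other.inter_level
            and self.seed == other.seed
        )


@dataclass
class StagePair:
    """Two TruthModels linked by a per-bin compartment switch mask."""

    truth_gv: TruthModel
    truth_mii: TruthModel
    switch_mask: np.ndarray  # values in SWITCH_CLASSES

    def __post_init__(self):
        self.switch_mask = np.asarray(self.switch_mask, dtype="U2")
        l1 = self.truth_gv.compartment_labels
        l2 = self.truth_mii.compartment_labels
        expect = np.where(
            l1 == "A", np.where(l2 == "A", "AA", "AB"),
            np.where(l2 == "A", "BA", "BB"),
        )
        if not np.array_equal(self.switch_mask, expect):
            raise ValueError("switch_mask inconsistent with stage labels")

    def class_fractions(self) -> dict[str, float]:
        n = len(self.switch_mask)
        return {c: float(np.sum(self.switch_mask == c)) / n for c in SWITCH_CLASSES}


# ===================================================================== truth
def make_truth(
    n_bins: int = 1000,
    bin_size: int = 20_000,
    n_chroms: int = 1,
    compartment_run: int = 25,
    n_tads: int = 20,
    tad_enrichment: float = 2.0,
    n_peis: int = 0,
    pei_fold: float = 3.0,
    decay_exponent: float = -1.0,
    plaid_strength: float = 1.5,
    bias_sd: float = 0.2,
    base_depth: float = 800.0,
    inter_level: float = 13.0,
    seed: int = 0,
) -> TruthModel:
    """Draw a random TruthModel with planted structure.

    Compartments are contiguous A/B runs of geometric length (mean
    ``compartment_run`` bins, megabase-scale plaid at the default 20 kb
    bins); TADs tile the genome with gaps; coverage bias is log-normal;
    PEI promoter/enhancer anchors are placed 2-100 bins apart.
    """
    rng = np.random.default_rng(seed)
    per = n_bins // n_chroms
    partition = [(f"chr{k + 1}", per) for k in range(n_chroms)]
    partition[-1] = (partition[-1][0], per + n_bins - per * n_chroms)

    labels = np.empty(n_bins, dtype="U1")
    pos, cur = 0, rng.choice(["A", "B"])
    while pos < n_bins:
        run = int(rng.geometric(1.0 / compartment_run))
        labels[pos: pos + run] = cur
        cur = "A" if cur == "B" else "B"
        pos += run
    # guarantee both classes exist
    if len(np.unique(labels)) == 1:
        labels[: n_bins // 2] = "A"
        labels[n_bins // 2:] = "B"

    bounds = []
    off = 0
    for _, n in partition:
        bounds.append((off, off + n))
        off += n

    tads = []
    if n_tads > 0:
        per_chrom = [n_tads // len(partition)] * len(partition)
        per_chrom[0] += n_tads - sum(per_chrom)
        for (a, b), k in zip(bounds, per_chrom):
            span = b - a
            k = min(k, (span - 1) // 4)  # >= 2 bins/domain plus >= k+1 gap bins
            if k <= 0:
                continue
            gap_total = max(k + 1, min(int(0.1 * span), span - 2 * k))
            dom_total = span - gap_total
            sizes = rng.multinomial(dom_total - 2 * k, np.full(k, 1.0 / k)) + 2
            gaps = rng.multinomial(gap_total - (k + 1), np.full(k + 1, 1.0 / (k + 1))) + 1
            cur = a
            for g, s in zip(gaps[:-1], sizes):
                cur += int(g)
                tads.append((cur, cur + int(s), float(tad_enrichment)))
                cur += int(s)

    peis = []
    if n_peis > 0:
        for _ in range(n_peis):
            ca, cb = bounds[int(rng.integers(len(bounds)))]
            p = int(rng.integers(ca, cb - 2))
            d = int(rng.integers(2, min(100, cb - p - 1) + 1))
            peis.append((p, p + d, float(pei_fold)))

    bias = np.exp(rng.normal(0.0, bias_sd, size=n_bins))
    return TruthModel(
        bin_size=bin_size,
        chrom_partition=partition,
        compartment_labels=labels,
        tads=tads,
        peis=peis,
        decay_exponent=decay_exponent,
        plaid_strength=plaid_strength,
        coverage_bias=bias,
        base_depth=base_depth,
        inter_level=inter_level,
        seed=seed,
    )


# ============================================================== expected map
def build_expected_map(truth: TruthModel) -> np.ndarray:
    """Dense expected intensity matrix of a TruthModel.

    Intra-chromosomal entry (i, j), |i-j| >= 1::

        base_depth * bias_i * bias_j * |i-j|**decay_exponent
                   * plaid_factor(i, j) * tad_factor(i, j) * pei_factor(i, j)

    where plaid_factor is ``plaid_strength`` for same-compartment pairs and
    ``1/plaid_strength`` otherwise, tad_factor is the domain enrichment when
    both bins lie in one planted TAD, and pei_factor the planted peak fold.
    Inter-chromosomal entries are ``inter_level * bias_i * bias_j``; the
    diagonal is 0.
    """
    n = truth.n_bins
    bias = truth.coverage_bias
    e = np.full((n, n), truth.inter_level)
    labels = truth.compartment_labels
    for a, b in truth.chrom_bounds():
        idx = np.arange(a, b)
        d = np.abs(idx[:, None] - idx[None, :]).astype(float)
        with np.errstate(divide="ignore"):
            decay = d ** truth.decay_exponent
        decay[d == 0] = 0.0
        same = labels[a:b, None] == labels[None, a:b]
        plaid = np.where(same, truth.plaid_strength, 1.0 / truth.plaid_strength)
        e[a:b, a:b] = truth.base_depth * decay * plaid
    for ta, tb, enr in truth.tads:
        e[ta:tb, ta:tb] *= enr
    for p, q, f in truth.peis:
        e[p, q] *= f
        e[q, p] *= f
    e *= bias[:, None] * bias[None, :]
    np.fill_diagonal(e, 0.0)
    if not np.all(np.isfinite(e)):
        raise AssertionError("expected map must be finite")
    return e


def sample_contacts(expected: np.ndarray, truth: TruthModel, seed: int
                    ) -> ContactMatrix:
    """Poisson-sample integer contacts from an expected intensity matrix.

    Each upper-triangle entry is drawn independently; the matrix is then
    symmetrized. Reproducible for a fixed seed.
    """
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0) or not np.all(np.isfinite(expected)):
        raise ValueError("expected map must be finite and non-negative")
    rng = np.random.default_rng(seed)
    n = expected.shape[0]
    upper = np.triu(rng.poisson(expected), 0)
    dense = upper + np.triu(upper, 1).T
    return ContactMatrix.from_dense(truth.genome, dense, raw=True)


def simulate_matrix(truth: TruthModel, seed: int) -> ContactMatrix:
    """Convenience: expected map + Poisson sampling in one call."""
    return sample_contacts(build_expected_map(truth), truth, seed)


# ==================================================================== pairs
PAIR_COLUMNS = [
    "readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2",
    "frag1", "frag2",
]


def emit_pairs(
    matrix: ContactMatrix,
    truth: TruthModel,
    seed: int,
    contamination: float = 0.0,
    frag_size: int = 500,
) -> pd.DataFrame:
    """Expand a contact matrix into read-pair records.

    Positions are uniform within bins, strands random, fragment IDs derived
    from position (``pos // frag_size`` per chromosome). With
    ``contamination = 0`` re-binning the pairs reproduces the matrix
    exactly; with ``contamination = c`` each record is independently
    replaced, with probability c, by a planted invalid pair (dangling-end,
    self-circle or re-ligation) whose readID carries its type.
    """
    if not (0 <= contamination < 1):
        raise ValueError("contamination must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genome = matrix.genome
    coo = matrix.data.tocoo()
    rows = []
    k = 0
    for bi, bj, c in zip(coo.row, coo.col, coo.data):
        c = int(c)
        if c == 0:
            continue
        ch1, s1, e1 = genome.bin_location(int(bi))
        ch2, s2, e2 = genome.bin_location(int(bj))
        for _ in range(c):
            if contamination > 0 and rng.random() < contamination:
                rows.append(_invalid_pair(rng, genome, frag_size, k))
                k += 1
                continue
            for _attempt in range(20):
                p1 = int(rng.integers(s1, e1))
                p2 = int(rng.integers(s2, e2))
                f1, f2 = p1 // frag_size, p2 // frag_size
                # keep planted-valid pairs classifiable as valid
                if ch1 != ch2 or abs(f1 - f2) > 1:
                    break
            st1 = "+" if rng.random() < 0.5 else "-"
            st2 = "+" if rng.random() < 0.5 else "-"
            rows.append((f"pair{k}", ch1, p1, ch2, p2, st1, st2, f1, f2))
            k += 1
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return df


def _invalid_pair(rng, genome: BinnedGenome, frag_size: int, k: int):
    """One planted invalid read pair of a random type."""
    kind = ("dangling_end", "self_circle", "re_ligation")[int(rng.integers(3))]
    chrom = genome.chroms[int(rng.integers(len(genome.chroms)))]
    length = genome.chrom_sizes[chrom]
    if kind in ("dangling_end", "self_circle"):
        frag = int(rng.integers(0, max(1, length // frag_size)))
        lo = frag * frag_size
        hi = min(lo + frag_size, length)
        p1, p2 = sorted(int(rng.integers(lo, hi)) for _ in range(2))
        strands = ("+", "-") if kind == "dangling_end" else ("-", "+")
        return (f"{kind}{k}", chrom, p1, chrom, p2, strands[0], strands[1],
                frag, frag)
    frag = int(rng.integers(0, max(1, length // frag_size - 1)))
    p1 = int(rng.integers(frag * frag_size, min((frag + 1) * frag_size, length)))
    lo2 = (frag + 1) * frag_size
    p2 = int(rng.integers(lo2, min(lo2 + frag_size, length)))
    st1 = "+" if rng.random() < 0.5 else "-"
    st2 = "+" if rng.random() < 0.5 else "-"
    return (f"{kind}{k}", chrom, p1, chrom, p2, st1, st2, frag, frag + 1)


def write_pairs(df: pd.DataFrame, path: str | Path, genome: BinnedGenome = None
                ) -> None:
    """Write pair records as 4DN-style headered text."""
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: " + " ".join(PAIR_COLUMNS) + "\n")
        if genome is not None:
            for c in genome.chroms:
                fh.write(f"#chromsize: {c} {genome.chrom_sizes[c]}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=PAIR_COLUMNS,
        dtype={"chrom1": str, "chrom2": str},
    )
    return df


# ============================================================== stage pairs
def make_stage_pair(
    base_truth: TruthModel,
    frac_a_to_b: float,
    frac_b_to_a: float,
    seed: int,
    mean_run: int = 5,
) -> StagePair:
    """Derive a second stage by flipping contiguous compartment runs.

    Runs have geometric length (mean ``mean_run`` bins) and are flipped
    until the requested genome fraction is reached; realized fractions land
    within one run length of the request.
    """
    if frac_a_to_b < 0 or frac_b_to_a < 0 or frac_a_to_b + frac_b_to_a >= 1:
        raise ValueError("switch fractions must be >= 0 and sum below 1")
    rng = np.random.default_rng(seed)
    labels1 = base_truth.compartment_labels.copy()
    n = len(labels1)
    n_a = int(np.sum(labels1 == "A"))
    n_b = n - n_a
    targets = {"A": int(round(frac_a_to_b * n)), "B": int(round(frac_b_to_a * n))}
    if targets["A"] > n_a or targets["B"] > n_b:
        raise ValueError("requested switch fraction exceeds available bins")

    labels2 = labels1.copy()
    flipped = np.zeros(n, dtype=bool)
    for source, target in targets.items():
        dest = "B" if source == "A" else "A"
        done = 0
        attempts = 0
        while done < target:
            attempts += 1
            if attempts > 100 * n:
                raise RuntimeError("could not place requested switch runs")
            candidates = np.flatnonzero((labels1 == source) & ~flipped)
            if len(candidates) == 0:
                break
            start = int(candidates[rng.integers(len(candidates))])
            run = int(rng.geometric(1.0 / mean_run))
            end = start
            while (
                end < n
                and end - start < run
                and labels1[end] == source
                and not flipped[end]
            ):
                end += 1
            labels2[start:end] = dest
            flipped[start:end] = True
            done += end - start
    mask = np.where(
        labels1 == "A", np.where(labels2 == "A", "AA", "AB"),
        np.where(labels2 == "A", "BA", "BB"),
    )
    truth2 = replace(
        base_truth,
        compartment_labels=labels2,
        coverage_bias=base_truth.coverage_bias.copy(),
        tads=list(base_truth.tads),
        peis=list(base_truth.peis),
        seed=base_truth.seed + 1,
    )
    return StagePair(base_truth, truth2, mask)


def shift_tad_boundaries(
    truth: TruthModel, frac: float, min_shift_bins: int, seed: int
) -> tuple[TruthModel, list[int]]:
    """Move a fraction of TAD boundaries by >= ``min_shift_bins`` bins.

    Returns the altered model and the list of original boundary bins that
    were moved (for scoring differential-boundary detection).
    """
    rng = np.random.default_rng(seed)
    tads = [list(t) for t in truth.tads]
    n_move = max(1, int(round(frac * len(tads))))
    moved_idx = rng.choice(len(tads), size=n_move, replace=False)
    moved_bins = []
    bounds = truth.chrom_bounds()
    for k in sorted(moved_idx):
        a, b, e = tads[k]
        ca = next(x for x, y in bounds if x <= a < y)
        prev_end = tads[k - 1][1] if k > 0 else ca
        # shrink from the left: moves the start boundary inward
        shift = min_shift_bins + int(rng.integers(0, 2))
        if b - (a + shift) >= 3:
            moved_bins.append(a)
            tads[k][0] = a + shift
        elif a - shift >= prev_end:
            moved_bins.append(a)
            tads[k][0] = a - shift
    truth2 = replace(
        truth,
        tads=[tuple(t) for t in tads],
        compartment_labels=truth.compartment_labels.copy(),
        coverage_bias=truth.coverage_bias.copy(),
        peis=list(truth.peis),
        seed=truth.seed + 1,
    )
    return truth2, moved_bins


# =============================================================== expression
def simulate_expression(
    truth: TruthModel,
    n_genes: int,
    seed: int,
    mu_a: float = 4.0,
    mu_b: float = 2.0,
    sigma: float = 1.0,
    labels: np.ndarray = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place genes uniformly and draw compartment-coupled expression.

    log2 expression ~ Normal(mu_a, sigma) for genes whose TSS bin is in
    compartment A and Normal(mu_b, sigma) in B (mu_a > mu_b); FPKM =
    2**log2expr. Returns (expression table, BED6-like gene annotation with
    a ``tss`` column).
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if mu_a <= mu_b:
        raise ValueError("mu_a must exceed mu_b")
    rng = np.random.default_rng(seed)
    genome = truth.genome
    comp = labels if labels is not None else truth.compartment_labels
    chrom_names = genome.chroms
    sizes = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=float)
    probs = sizes / sizes.sum()
    genes = []
    for k in range(n_genes):
        ci = int(rng.choice(len(chrom_names), p=probs))
        chrom = chrom_names[ci]
        length = genome.chrom_sizes[chrom]
        tss = int(rng.integers(0, length))
        strand = "+" if rng.random() < 0.5 else "-"
        body = int(rng.integers(10_000, 200_000))
        if strand == "+":
            start, end = tss, min(tss + body, length)
        else:
            start, end = max(tss - body, 0), tss + 1
        genes.append((chrom, start, end, f"gene{k:05d}", 0, strand, tss))
    gene_df = pd.DataFrame(
        genes, columns=["chrom", "start", "end", "gene", "score", "strand", "tss"]
    )
    bins = np.array(
        [genome.bin_index(c, t) for c, t in zip(gene_df["chrom"], gene_df["tss"])]
    )
    mu = np.where(comp[bins] == "A", mu_a, mu_b)
    log_expr = rng.normal(mu, sigma)
    expr_df = pd.DataFrame(
        {"gene": gene_df["gene"], "fpkm": 2.0 ** log_expr,
         "tss_bin": bins, "compartment": comp[bins]}
    )
    return expr_df, gene_df


def simulate_stage_expression(
    pair: StagePair, n_genes: int, seed: int, **kwargs
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared gene placement, per-stage expression coupled to each stage's
    compartments. Returns (table with fpkm_gv/fpkm_mii, gene annotation)."""
    expr1, genes = simulate_expression(pair.truth_gv, n_genes, seed, **kwargs)
    rng = np.random.default_rng(seed + 1)
    comp2 = pair.truth_mii.compartment_labels[expr1["tss_bin"].to_numpy()]
    mu_a = kwargs.get("mu_a", 4.0)
    mu_b = kwargs.get("mu_b", 2.0)
    sigma = kwargs.get("sigma", 1.0)
    mu = np.where(comp2 == "A", mu_a, mu_b)
    fpkm2 = 2.0 ** rng.normal(mu, sigma)
    table = pd.DataFrame(
        {
            "gene": expr1["gene"],
            "fpkm_gv": expr1["fpkm"],
            "fpkm_mii": fpkm2,
            "tss_bin": expr1["tss_bin"],
        }
    )
    return table, genes


def simulate_gc(
    truth: TruthModel, seed: int, gc_a: float = 0.46, gc_b: float = 0.38,
    sd: float = 0.01,
) -> np.ndarray:
    """Per-bin GC fraction, higher in compartment A (used to orient PC1)."""
    rng = np.random.default_rng(seed)
    base = np.where(truth.compartment_labels == "A", gc_a, gc_b)
    return np.clip(base + rng.normal(0.0, sd, size=truth.n_bins), 0.05, 0.95)
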