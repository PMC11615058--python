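# Methods

This note documents the models, parameter choices and numerical decisions
behind `hicstage`, and what the simulation-based verification does and
does not establish.

## Synthetic data model

Each condition is a `TruthModel`. The expected intensity of an
intra-chromosomal bin pair (i, j), |i−j| ≥ 1, is

```
E_ij = base_depth · bias_i · bias_j · |i−j|^α · plaid(i,j) · tad(i,j) · pei(i,j)
```

with `plaid = plaid_strength` for same-compartment pairs and its
reciprocal otherwise, `tad` the planted intra-domain enrichment when both
bins share a domain, and `pei` a focal fold on a planted anchor pair.
Inter-chromosomal pairs have constant unbiased intensity `inter_level ·
bias_i · bias_j`; the diagonal is 0. Counts are independent Poisson draws
on the upper triangle, then symmetrized.

Defaults and their grounds:

- **α = −1.0** — the canonical Hi-C contact-probability decay.
- **plaid_strength = 1.5, TAD enrichment = 2.0, PEI fold = 3.0** — strong
  enough to be recoverable, weak enough that recovery is non-trivial.
- **base_depth = 800** (expected contacts of an unbiased pair at 1-bin
  distance). Derived from the sequencing scale of a deep two-library Hi-C
  study (~8×10⁸ usable contacts over a ~1.5×10⁵-bin genome at 20 kb):
  under the |i−j|⁻¹ decay this reproduces a per-bin marginal of ~10⁴,
  which also places the 20 kb resolution just past the 1,000-contacts/bin
  threshold that the resolution-assessment rule checks.
- **inter_level = 13** — calibrates the cis fraction to roughly the 60%
  observed in deep datasets on a desk-scale two-chromosome genome.
- **coverage bias** — log-normal, σ = 0.2.
- **compartment runs** — geometric with mean 25 bins (≈ 0.5 Mb at 20 kb),
  giving megabase-scale plaid; **switch runs** geometric with mean 5 bins,
  because stage transitions are region-level events, not independent bins.
- **expression** — log₂ FPKM ~ N(4, 1) for genes whose TSS bin is in A and
  N(2, 1) in B; GC ~ N(0.46, 0.01) in A vs N(0.38, 0.01) in B, which is
  what orients PC1.

What the generator does **not** emulate: sub-bin distance structure (pair
positions are uniform within bins, so short-range cis fractions are a
binning artifact, not biology), hierarchical/nested domains, replication
timing, sequence-level effects, or library-specific artifacts beyond the
three planted invalid-pair classes. Passing recovery tests therefore
demonstrates the *estimators* are correct and well-calibrated under the
stated statistical structure — not that real granulosa-cell maps satisfy
that structure.

## Pair filtering

Community (Juicer-style) conventions: same restriction fragment with
inward-facing strands → dangling end; outward-facing → self-circle;
adjacent fragments on one chromosome → re-ligation; all else valid. Pairs
without fragment annotation can only be processed in position-only mode
(no filtering), and the classifier says so rather than guessing.

## Balancing

**ICE** iterates `W ← W / (s sᵀ)` with `s` the mean-normalized marginal
vector until the coefficient of variation of marginals falls below `tol`
(default 1e−5, 200 iterations). **KR-style balancing** finds the positive
diagonal `x` with `x_i (A x)_i = 1` by the damped fixed point
`x ← sqrt(x / (A x))`; for symmetric irreducible non-negative matrices
this is the unique doubly stochastic scaling, the same point a
Knight–Ruiz Newton solver reaches, so equivalence is asserted against an
independent alternating-IPF oracle rather than against a specific solver
trajectory. Bins with zero marginal, or below the 2nd percentile of
non-zero marginals, are masked before balancing to prevent divergence;
reducible inputs are rejected with the component sizes named.

Both balancers target equalized marginals, so their outputs are
entrywise proportional; the pipeline uses KR (plus the between-sample
quantile step) for TAD and PEI calling, with ICE available by flag.

**Quantile normalization** equalizes, per intra-chromosomal distance
stratum, the value distributions across samples by rank-wise assignment of
the samples' mean sorted values. Ties are broken by genomic position
(deterministic); this makes the per-stratum distributions *exactly*
identical afterwards, which is the property the pipeline relies on. No
batch-covariate step is included — at desk scale there are no batches.

**SCC** smooths each intra map with a (2h+1)-wide mean filter (default
h = 2 bins), computes a Pearson correlation per bin distance up to 5 Mb,
and combines them weighted by stratum size × the geometric mean of the two
stratum standard deviations; self-comparison gives exactly 1.

## Compartments

Per chromosome: distance-decay expected (mean observed per distance),
O/E, Pearson correlation matrix over usable bins, and PC1 of the centered
correlation matrix. The distance-based expected is used here because a
marginal-product expected cannot remove distance decay, which would
otherwise dominate PC1; the marginal-product model (`E_ij = f_i f_j T`) is
implemented separately for inter-chromosomal normalization. The
self-contact diagonal of the O/E is replaced by each row's off-diagonal
mean before correlating, so structureless maps degenerate cleanly (and
are reported as such) instead of correlating on diagonal artifacts. PC1's
sign is oriented so it correlates non-negatively with GC; without a GC
track the profile is flagged unoriented and switch detection refuses it.

A switch requires both a PC1 sign change and |ΔPC1| above a variability
floor (default 0.4 × the stage-1 PC1 standard deviation) — a transparent,
tunable stand-in for an external variability test. Runs of one class merge
into regions; genes are attached by body overlap.

## TADs

**DI** uses the chi-square-like Dixon statistic with a 1 Mb window —
50 bins at the 20 kb working resolution, keeping the canonical window
measured in bins rather than bp; at 100 bins the statistic loses locality
against ~1 Mb domains. **HMM segmentation**: the DI is winsorized at the
0.5th/99.5th percentiles (chromosome-edge bins produce extreme values)
and standardized; a 3-state Gaussian HMM is initialized on the tail
deciles with per-group variances and fit by EM (deterministic given the
data; states identified by fitted-mean order). A domain runs from the
start of a downstream-biased run to the end of the next upstream-biased
run; each edge is then refined to the DI extremum within ±5 bins (ties
toward the HMM edge), the width of a typical inter-domain gap, because
the DI physically peaks at the first/last in-domain bin. **IS** uses a
500 kb window with boundaries as prominence-filtered local minima,
searched only where the window fits. Combined calling takes domains from
the HMM, single-bin boundary elements where IS minima corroborate domain
edges, and long `none`-state stretches as unorganized; output intervals
never overlap.

Stage comparison matches boundaries one-to-one within ±1 bin (Jaccard =
matched / union), correlates the DI tracks by Spearman, and scores each
consensus boundary by the z-score of its IS change against the genome-wide
ΔIS distribution; |z| > 1.5 (the conventional default) marks differential
boundaries, and domains with a differential edge are differential TADs.

Known limitation: on maps carrying both plaid compartments and TADs the
caller reports extra boundaries at compartment transitions — those are
genuine insulation discontinuities of the simulated map, so domain counts
on combined maps exceed the planted TAD count. The boundary-recovery
guarantees are therefore stated on TAD-only maps.

## PEIs

Promoter windows are strand-relative (−2000/+500 around the TSS, mirrored
on the minus strand) and clipped to the chromosome. The expected model is
two-level: per-TAD least-squares fits of `log(mean count)` vs
`log(distance)`, falling back to a per-chromosome background fit outside
domains or where a domain has under three occupied distances. Tests are
upper-tail Poisson on balanced counts rescaled to the raw sequencing depth
(balancing to row sums 1 destroys the count scale a Poisson model needs)
and rounded to the nearest integer; BH correction runs across all promoter
tests, and calls must satisfy q < 0.01, distance ≥ 15 kb and observed >
expected — asserted on every output. Promoters are processed in 20 Mb
chunks with 10 Mb steps purely for memory locality; results are invariant
to the chunking and a test asserts it. The Poisson choice (rather than a
Gaussian on residuals) is deliberate: the verification surface is FDR
control on null simulations, not any specific p-value.

On maps with plaid compartments the two-level model does not capture
same-compartment enrichment, so compartment-driven pairs appear among the
calls; planted-peak recovery and null error control are therefore scored
on compartment-free maps, and the combined-map outputs should be read
with that confound in mind.

## Integration

Gene-to-bin assignment uses the TSS for compartment contrasts and body
overlap for switch-region gene lists. The differential-expression flag
for the overlap analysis is |log₂((FPKM₂+1)/(FPKM₁+1))| ≥ 1. All joins
are loss-accounted. The A-vs-B contrast reports medians and a two-sided
rank-sum test without a built-in directional claim, and the GC/expression
correlation asserts no sign — in the simulation both are driven by the
planted A-compartment coupling. 2^−ΔΔCt averages replicate Ct per
(group, gene), normalizes by the reference gene and then the calibrator
group; it is invariant to group-wide Ct offsets.

## Numerical and degenerate-input policy

Zero-variance strata (SCC) are skipped with weight 0 and logged; all-zero
matrices, reducible matrices, empty TAD sets, missing reference genes and
infeasible switch fractions raise errors naming the problem; undefined
quantities (D-score of a contact-free domain, A-B index of an isolated
bin) are NaN and flagged, never silently zero. All stochastic steps take
explicit seeds; the pipeline manifest records the config hash and seed,
and re-running with the same config is byte-identical.

## Verification scales

The test suite and the acceptance script run at desk scale: 1,000-bin
chromosomes for compartment/switch/TAD recovery, 500-bin maps × 10 seeds
for PEI error control, 150-bin maps × 20 trials for SCC ordering and
D-score ordering, 50-bin matrices for balancing oracles. These sizes give
each check enough events to be statistically meaningful while keeping the
whole verification under a minute.
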