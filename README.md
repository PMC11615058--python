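# hicstage

Comparative Hi-C analysis of two cellular conditions — written around the
contrast between granulosa cells of germinal-vesicle (GV) and metaphase-II
(MII) stage ovarian follicles, but applicable to any two-condition design.
The package covers the full chain from annotated read pairs to integrated
chromatin/expression statistics:

1. **contacts** — pair-level quality filters (dangling-end, self-circle,
   re-ligation), binning into symmetric contact matrices, cis/trans
   statistics, and the depth-based resolution assessment (smallest bin size
   at which >80% of bins collect ≥1,000 contacts).
2. **normalization** — ICE and KR matrix balancing, per-distance quantile
   normalization between samples, and HiCRep-style stratum-adjusted
   correlation (SCC) for reproducibility.
3. **compartments** — O/E transformation, Pearson correlation matrix, A/B
   calling from the first principal component (sign oriented by GC
   content), the A-B contact index, and stage-switch classification
   (AA / BB / A→B / B→A) with merged regions and embedded genes.
4. **tads** — directionality index (DI) segmented by a 3-state Gaussian
   HMM, insulation score (IS), domain/boundary/unorganized classification,
   per-domain D-score, compartment labeling (>70% rule), and two-stage
   comparison (boundary Jaccard, DI Spearman, standardized ΔIS boundary
   score with the 1.5 default threshold).
5. **pei** — promoter–enhancer interaction calling: promoter windows
   (TSS−2000 to TSS+500, strand-relative), a domain-aware power-law
   expected model, upper-tail Poisson tests with Benjamini–Hochberg
   correction, and the FDR < 0.01 / distance ≥ 15 kb filters; summary
   statistics and per-gene two-stage deltas.
6. **integration** — GC/expression correlation, A-vs-B expression
   contrast, the three-way dynamic-gene overlap (compartment switch ×
   differential TAD × differential expression), and qPCR 2^−ΔΔCt.

Because deposited sequencing data are not required, a **synthetic-data
generator** (`hicstage.synthetic`) produces two-condition contact maps with
*planted* ground truth — power-law distance decay, plaid compartments,
block-diagonal TAD enrichment, focal promoter–enhancer peaks, per-bin
coverage bias, Poisson noise, and compartment-coupled expression — so every
stage is verified by recovery of known structure.

## The core statistics

With A (B) the contact sum from bin *i* into the upstream (downstream)
window and E = (A+B)/2, the directionality index is

```
DI(i) = sign(B − A) · [ (A−E)²/E + (B−E)²/E ]
```

The insulation score is `IS(i) = log2(s_i / ⟨s⟩)` for the mean contact
count `s_i` in the w×w square crossing bin *i*. A domain's D-score is the
fraction of its total contact mass that is intra-domain. Compartments are
the sign of the leading principal component of the per-chromosome Pearson
correlation matrix of the distance-normalized (O/E) map. PEI significance
is `P(Poisson(expected) ≥ observed)` under a per-domain fit of
`log E = a + α·log d`, BH-corrected over all promoter tests.

## Worked example

```
python analysis/01_simulate_two_stage_dataset.py
python analysis/04_call_compartments_and_switches.py
```

prints, on the default desk-scale dataset (600 bins × 20 kb, two
chromosomes, ~6.5 M contacts per stage, planted 10% A→B and 7% B→A
switches):

```
gv: compartment A 56.7% / B 43.3%; planted-label accuracy 99.5%
mii: compartment A 53.2% / B 46.8%; planted-label accuracy 99.5%
switch classes (called vs planted, % of genome):
  AA: called  46.7%  planted  47.0%  embedded genes 364
  BB: called  36.5%  planted  36.0%  embedded genes 325
  AB: called  10.0%  planted  10.0%  embedded genes 115
  BA: called   6.8%  planted   7.0%  embedded genes 102
```

i.e. the caller labels 99.5% of bins to their planted compartment and
recovers the planted switch fractions to within a fraction of a percentage
point. The remaining numbered scripts (`02`–`07`) run pair QC, balancing
and reproducibility, TAD calling and comparison, PEI calling, and
expression integration, writing their tables under `results/analysis/`.

A `hicstage` command-line tool exposes each stage
(`simulate | bin | normalize | compartments | tads | pei | compare | run`)
over a YAML config; `hicstage run --seed 1 --out out/` executes the whole
two-stage comparison end to end and writes a manifest with the config
hash, seed, and per-stage counts.

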