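"""Shared paths and dataset configuration for the numbered analysis scripts.

The drivers emulate a two-stage (GV vs MII granulosa-cell) Hi-C comparison
on a desk-scale synthetic genome: 2 chromosomes x 300 bins at 20 kb, depth
matched to ~10,000 contacts per bin, 12 planted TADs, 20 planted
promoter-enhancer peaks, 10% A->B and 7% B->A planted compartment switches.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "analysis" / "data"
OUT = ROOT / "results" / "analysis"

SEED = 20261001

SIM = dict(
    n_bins=600,
    n_chroms=2,
    bin_size=20_000,
    n_tads=12,
    n_peis=20,
    n_genes=600,
    frac_a_to_b=0.10,
    frac_b_to_a=0.07,
)
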