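"""Simulate the two-stage Hi-C dataset with planted ground truth.

Generates the GV/MII truth pair (shared TADs and peaks, planted
compartment switches), Poisson contact maps, a shallow read-pair file for
the pair-level analyses, gene annotation, stage-coupled expression, and a
GC track. Everything downstream loads these files.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA, SEED, SIM

from hicstage import io, synthetic as syn


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    truth = syn.make_truth(
        n_bins=SIM["n_bins"], n_chroms=SIM["n_chroms"],
        bin_size=SIM["bin_size"], n_tads=SIM["n_tads"], n_peis=SIM["n_peis"],
        seed=SEED,
    )
    pair = syn.make_stage_pair(truth, SIM["frac_a_to_b"], SIM["frac_b_to_a"],
                               seed=SEED + 1)
    pair.truth_gv.to_json(DATA / "truth_gv.json")
    pair.truth_mii.to_json(DATA / "truth_mii.json")
    genome = truth.genome
    io.write_chrom_sizes(genome, DATA / "chrom.sizes")

    for stage, t, s in (("gv", pair.truth_gv, SEED + 2),
                        ("mii", pair.truth_mii, SEED + 3)):
        m = syn.simulate_matrix(t, s)
        m.write(DATA / f"matrix_raw_{stage}")
        print(f"{stage}: {int(m.total()):,} contacts "
              f"({m.total() / truth.n_bins:,.0f} per bin-row)")
    # a replicate of GV for reproducibility scoring
    syn.simulate_matrix(pair.truth_gv, SEED + 4).write(DATA / "matrix_raw_gv_rep")

    # shallow pair-level file (depth scaled down, cis/trans balance kept)
    shallow = syn.make_truth(
        n_bins=SIM["n_bins"], n_chroms=SIM["n_chroms"],
        bin_size=SIM["bin_size"], n_tads=SIM["n_tads"],
        base_depth=60.0, inter_level=13.0 * 60.0 / 800.0, seed=SEED,
    )
    m_shallow = syn.simulate_matrix(shallow, SEED + 5)
    pairs = syn.emit_pairs(m_shallow, shallow, SEED + 6, contamination=0.05)
    syn.write_pairs(pairs, DATA / "pairs_shallow.pairs", genome)
    print(f"shallow pair file: {len(pairs):,} records (5% planted invalid)")

    expr, genes = syn.simulate_stage_expression(pair, SIM["n_genes"], SEED + 7)
    io.write_genes_bed6(genes, DATA / "genes.bed")
    expr.to_csv(DATA / "expression.tsv", sep="\t", index=False)
    gc = syn.simulate_gc(pair.truth_gv, SEED + 8)
    io.write_bedgraph(genome, gc, DATA / "gc.bedgraph")
    print(f"planted: {len(truth.tads)} TADs, {len(truth.peis)} PEIs, "
          f"switch fractions {pair.class_fractions()}")


if __name__ == "__main__":
    main()
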