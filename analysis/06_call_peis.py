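"""Call promoter-enhancer interactions per stage against the domain-aware
expected model, summarize them (within-TAD, short-range, promoter
skipping) and rank the genes gaining/losing PEIs between stages."""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA, OUT, SEED

from hicstage import io, pei, synthetic as syn, tads as tad
from hicstage.matrix import ContactMatrix


def main():
    genes = io.read_genes_bed6(DATA / "genes.bed")
    truth = {s: syn.TruthModel.from_json(DATA / f"truth_{s}.json")
             for s in ("gv", "mii")}

    peisets = {}
    for stage in ("gv", "mii"):
        raw = ContactMatrix.read(DATA / f"matrix_raw_{stage}")
        m = ContactMatrix.read(DATA / f"matrix_balanced_{stage}")
        m = pei.scale_to_depth(m, raw.total())
        di = tad.directionality_index(m)
        hmm = tad.fit_hmm(di, seed=SEED)
        ist = tad.insulation_score(m)
        ts = tad.call_tads(hmm, ist)
        promoters = pei.make_promoters(genes, m.genome)
        bg = pei.fit_domain_background(m, ts)
        ps = pei.call_peis(m, promoters, bg)
        peisets[stage] = (ps, ts, promoters)
        pei.write_bedpe(ps, OUT / f"peis_{stage}.bedpe")
        st = pei.pei_stats(ps, ts, promoters)
        print(f"{stage}: {st.total} PEIs over {st.genes_with_pei} genes "
              f"(of {ps.n_tests:,} tests); "
              f"within TADs {st.frac_within_tad:.1%}, "
              f"within 100 kb {st.frac_short_range:.1%}, "
              f"skipping nearest promoter {st.frac_skipping:.1%}")

    # recovery of planted peaks (planted at arbitrary bins, so score only
    # peaks whose promoter anchor falls in a tested promoter bin)
    ps_gv, _, promoters = peisets["gv"]
    tested_bins = set(b for bins in promoters["bins"] for b in bins)
    testable = [(p, q) for p, q, _ in truth["gv"].peis
                if p in tested_bins or q in tested_bins]
    called = set(zip(ps_gv.table["promoter_bin"], ps_gv.table["enhancer_bin"]))
    if testable:
        hits = np.mean([(p, q) in called or (q, p) in called
                        for p, q in testable])
        print(f"planted peaks with a testable promoter anchor recovered: "
              f"{hits:.0%} ({len(testable)} testable)")

    delta, losers, gainers = pei.compare_pei_sets(peisets["gv"][0],
                                                  peisets["mii"][0])
    delta.to_csv(OUT / "pei_gene_delta.tsv", sep="\t", index=False)
    print("top PEI losers (GV -> MII):",
          ", ".join(f"{r.gene} ({r.delta:+d})" for r in
                    losers.head(5).itertuples()))
    print("top PEI gainers (GV -> MII):",
          ", ".join(f"{r.gene} ({r.delta:+d})" for r in
                    gainers.head(5).itertuples()))


if __name__ == "__main__":
    main()
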