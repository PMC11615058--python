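"""Pair-level quality control: invalid-pair filtering, cis/trans statistics
and the depth-based resolution assessment on the shallow pair file."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA, OUT

from hicstage import contacts, synthetic as syn
from hicstage.genome import BinnedGenome


def main():
    pairs = syn.read_pairs(DATA / "pairs_shallow.pairs")
    genome = BinnedGenome.from_chrom_sizes_file(DATA / "chrom.sizes", 20_000)

    classes = contacts.classify_pairs(pairs)
    counts = classes.value_counts()
    print("pair classification:")
    for cls, n in counts.items():
        print(f"  {cls:13s} {n:8,d} ({n / len(pairs):.1%})")

    matrix, stats = contacts.bin_contacts(pairs, genome, keep_only_valid=True)
    print(f"kept {stats.valid_pairs:,}/{stats.total_pairs:,} pairs; "
          f"cis {stats.cis_fraction:.1%}, "
          f"cis > 20 kb {stats.cis_long_fraction:.1%}")

    sizes = dict(pd.read_csv(DATA / "chrom.sizes", sep="\t", header=None,
                             names=["c", "l"]).itertuples(index=False))
    kept = pairs[classes == contacts.VALID]
    table, optimal = contacts.resolution_assessment(
        kept, sizes, [10_000, 20_000, 40_000, 80_000]
    )
    table.to_csv(OUT / "resolution_assessment.tsv", sep="\t", index=False)
    print("resolution assessment (fraction of bins with >= 1,000 contacts):")
    print(table.to_string(index=False))
    print(f"optimal bin size at this depth: "
          f"{optimal if optimal else 'none reaches 80%'}")

    summary = pd.DataFrame([{
        "total_pairs": stats.total_pairs,
        "valid_pairs": stats.valid_pairs,
        "cis_fraction": stats.cis_fraction,
        "cis_long_fraction": stats.cis_long_fraction,
        **{f"n_{c}": int(counts.get(c, 0)) for c in contacts.PAIR_CLASSES},
    }])
    summary.to_csv(OUT / "pair_qc_summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
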