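#!/usr/bin/env python
"""Scan deduced proteins for CD-epitope cores and annotate their context.

Scans the contig proteins from step 02 against the canonical nine-core
registry, then annotates the two published repeat peptides (the 17-mer
VIIb/γ2a/VI repeat and the proteolysis-resistant 26-mer): TG2 deamidation
markup, trypsin/chymotrypsin cleavage, and protease-resistant fragments.
"""

import argparse
from pathlib import Path

from gliascan.epitope_screen import (
    count_distinct_epitopes,
    count_instances,
    find_resistant_fragments,
    predict_cleavage,
    render_markup,
    scan_epitopes,
)
from gliascan.sequence_core import read_fasta

REPEAT_17MER = "QQPQQPFPQQPQQPFPQ"
RESISTANT_26MER = "FLQPQQPFPQQPQQPYPQQPQQPFPQ"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--proteins", type=Path, default=Path("results/contigs/proteins.fasta"))
    ap.add_argument("--outdir", type=Path, default=Path("results/epitopes"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for name, pep in (("17-mer repeat", REPEAT_17MER), ("26-mer", RESISTANT_26MER)):
        matches = scan_epitopes(pep)
        tryptic = predict_cleavage(pep, ["trypsin"])
        print(f"{name} {pep}:")
        print(f"  {count_instances(matches)} epitope instances, "
              f"{count_distinct_epitopes(matches)} distinct types, "
              f"{len(tryptic)} tryptic sites")
        print(f"  TG2 markup: {render_markup(pep)}  (Q̲=primary, q=moderate)")
        frags = find_resistant_fragments(pep, ["trypsin", "chymotrypsin_high"], 1)
        for f in frags:
            print(f"  resistant fragment [{f.start},{f.end}) holds {len(f.matches)} cores")

    with open(args.outdir / "matches.tsv", "w") as fh:
        fh.write("protein_id\tepitope\tstart\tend\tflank_left\tflank_right\n")
        n = 0
        for rec in read_fasta(args.proteins):
            for m in scan_epitopes(rec.seq):
                fh.write(f"{rec.id}\t{m.label}\t{m.start}\t{m.end}"
                         f"\t{m.flank_left}\t{m.flank_right}\n")
                n += 1
    print(f"{n} matches over contig proteins → {args.outdir}/matches.tsv")


if __name__ == "__main__":
    main()
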