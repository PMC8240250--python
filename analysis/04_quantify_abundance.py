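#!/usr/bin/env python
"""Quantify artifact abundance and demonstrate repeat-aware matching.

Relative abundance (split reads over junction-overlapping reads) is
computed per planted locus in the cDNA and dcDNA alignments and compared
with the slippage probability that generated them. A junction table with
boundaries shifted outwards into the repeat copies is then matched back
to the candidates, tolerating shifts of up to one repeat length per
side. Writes results/abundance.tsv and results/shift_matches.tsv.
"""
import argparse

import pandas as pd

from falsitron import SpliceJunction, genome_io, relative_abundance, shifted_junction_match


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", default="results/sim")
    parser.add_argument("--outdir", default="results")
    args = parser.parse_args()

    truth = pd.read_csv(f"{args.simdir}/truth.tsv", sep="\t")
    cdna = genome_io.read_alignments(f"{args.simdir}/reads_cdna.sam")
    dcdna = genome_io.read_alignments(f"{args.simdir}/reads_dcdna.sam")

    rows = []
    for r in truth.itertuples():
        j = SpliceJunction(r.chrom, r.start, r.end, r.strand)
        rows.append(
            {
                "locus_id": r.locus_id,
                "p_slip": r.p_slip,
                "abundance_cdna": relative_abundance(j, cdna),
                "abundance_dcdna": relative_abundance(j, dcdna),
            }
        )
    ab = pd.DataFrame(rows)
    ab.to_csv(f"{args.outdir}/abundance.tsv", sep="\t", index=False)
    print("per-locus artifact abundance (expected ~ p_slip):")
    print(ab.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

    # simulate the external-table situation: junctions recorded with
    # boundaries shifted outwards into the repeat copies
    match_rows = []
    for r in truth.itertuples():
        q = SpliceJunction(r.chrom, r.start, r.end, r.strand)
        rep = int(r.repeat_length)
        shift = max(1, rep // 2)
        observed = [
            SpliceJunction(r.chrom, r.start - shift, r.end + shift, r.strand)
        ]
        for m in shifted_junction_match(q, rep, observed):
            match_rows.append(
                {
                    "locus_id": r.locus_id,
                    "repeat_length": rep,
                    "shift5": m.shift5,
                    "shift3": m.shift3,
                    "length_delta": m.length_delta,
                }
            )
    matches = pd.DataFrame(
        match_rows,
        columns=["locus_id", "repeat_length", "shift5", "shift3", "length_delta"],
    )
    matches.to_csv(f"{args.outdir}/shift_matches.tsv", sep="\t", index=False)
    print(
        f"\nshifted-table matching: {len(matches)}/{(truth['repeat_length'] > 0).sum()} "
        "repeat-flanked loci re-identified despite boundary shifts"
    )
    print(matches.to_string(index=False))


if __name__ == "__main__":
    main()
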