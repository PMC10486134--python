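#!/usr/bin/env python
"""Call and classify SNVs of each isolate against the reference.

Reads results/data (run 01 first); writes per-isolate VCFs, the per-region
SNV/nonsynonymous summary table and substitution spectra under
results/variants/, and prints the headline numbers: genome-wide SNV totals,
nonsynonymous totals, and the dominant substitution types in the most
variable regions.
"""

import argparse
from pathlib import Path

import pandas as pd

from qbvgenomics.genome_io import read_fasta, read_region_table
from qbvgenomics.pairwise_align import AlignParams, global_align
from qbvgenomics.variants import (
    NONSYNONYMOUS,
    call_snvs,
    classify,
    spectrum,
    summarize_regions,
    write_vcf,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/variants"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    ref = read_fasta(args.datadir / "reference.fasta")[0]
    isolates = read_fasta(args.datadir / "isolates.fasta")
    table = read_region_table(args.datadir / "regions.tsv", reference_id=ref.id,
                              orf_end=None)

    snvs = {}
    for iso in isolates:
        aln = global_align(ref, iso, AlignParams(band_width=600))
        recs = classify(call_snvs(aln), ref, table)
        snvs[iso.id] = recs
        write_vcf(recs, ref, out / f"snvs_{iso.id}.vcf")
        ns = sum(r.effect == NONSYNONYMOUS for r in recs)
        print(f"{iso.id}: {len(recs)} SNVs, {ns} nonsynonymous")

    summary = summarize_regions(snvs, table)
    summary.to_csv(out / "region_snv_summary.tsv", sep="\t", index=False)
    tot = summary[summary.region == "total"].iloc[0]
    print(f"mean nonsynonymous per isolate: {tot['mean_nonsyn']}")

    rows = []
    for iso, recs in snvs.items():
        for region in ("NS3", "NS5", "AC+C"):
            sp = spectrum(recs, region=region, effect=NONSYNONYMOUS)
            if sp.total == 0:
                continue
            for t, c in sp.counts.items():
                if c:
                    rows.append({"isolate": iso, "region": region,
                                 "substitution": t, "count": c,
                                 "percent": sp.proportions[t]})
            top = max(sp.proportions, key=sp.proportions.get)
            print(f"{iso} {region}: dominant type {top} "
                  f"({sp.proportions[top]}% of {sp.total} nonsynonymous)")
    pd.DataFrame(rows).to_csv(out / "nonsyn_spectrum.tsv", sep="\t", index=False)
    print(f"tables under {out}")


if __name__ == "__main__":
    main()
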