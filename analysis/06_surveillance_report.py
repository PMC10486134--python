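#!/usr/bin/env python
"""Mosquito-collection composition and pool positivity of the 2021 survey.

Uses the packaged collection tallies (32,177 females, 15 counties) and the
pool screening outcome (3 virus-positive of 200 pools); writes
results/surveillance/report.tsv and prints the headline percentages.
"""

import argparse
from pathlib import Path

import pandas as pd

from qbvgenomics.datasets import (
    COLLECTION_TOTAL,
    N_POOLS,
    N_POSITIVE_POOLS,
    load_collection_tally,
)
from qbvgenomics.surveillance import PoolSummary, composition, positivity_rate


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/surveillance"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for level in ("genus", "species"):
        tally = load_collection_tally(level)
        pct = composition(tally, total=COLLECTION_TOTAL)
        for name, n in sorted(tally.counts.items(), key=lambda kv: -kv[1]):
            rows.append({"level": level, "taxon": name, "count": n,
                         "percent": pct[name]})
    rate = positivity_rate(PoolSummary(N_POOLS, N_POSITIVE_POOLS))
    rows.append({"level": "pools", "taxon": "positivity",
                 "count": N_POSITIVE_POOLS, "percent": rate})
    df = pd.DataFrame(rows)
    df.to_csv(out / "report.tsv", sep="\t", index=False)

    top = df[df.level == "genus"].iloc[0]
    dom = df[df.level == "species"].iloc[0]
    print(f"dominant genus: {top.taxon} ({top.percent}%)")
    print(f"dominant species: {dom.taxon} ({dom.percent}%)")
    print(f"pool positivity: {rate}% ({N_POSITIVE_POOLS}/{N_POOLS})")


if __name__ == "__main__":
    main()
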