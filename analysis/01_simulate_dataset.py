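#!/usr/bin/env python
"""Build the synthetic study dataset every later step analyzes.

Generates, with full ground truth under results/data/:
  - a 10,831-nt flavivirus-like reference (98-nt 5'UTR, 10,080-nt ORF in 11
    mature-peptide regions, 653-nt 3'UTR);
  - three isolates carrying the published per-region SNV counts of
    GZ21m081/GZ21m120/GZ21m167 against the VN180 prototype;
  - a pattern-free genome with one planted slippery site + hairpin at 3419;
  - an 8-taxon sequence set evolved along a known tree (JC, 0.02 subst/site
    per branch) for the phylogeny step.
"""

import argparse
import json
from pathlib import Path

from qbvgenomics.datasets import ISOLATES, snv_plant_spec
from qbvgenomics.genome_io import write_fasta, write_region_table
from qbvgenomics.synthetic_data import (
    evolve_on_tree,
    generate_reference,
    plant_prf_site,
    simulate_isolates,
)

TRUE_TREE = (
    "(((A:0.02,B:0.02):0.02,(C:0.02,D:0.02):0.02):0.02,"
    "((E:0.02,F:0.02):0.02,(G:0.02,H:0.02):0.02):0.02);"
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    truth = simulate_isolates(
        {iso: snv_plant_spec(iso) for iso in ISOLATES}, seed=args.seed
    )
    write_fasta([truth.reference], out / "reference.fasta")
    write_fasta(truth.isolates, out / "isolates.fasta")
    write_region_table(truth.region_table, out / "regions.tsv")
    truth.write_manifest(out / "truth.json")
    print(f"reference: {truth.reference.length} nt, "
          f"ORF {truth.region_table.orf_start}..{truth.region_table.orf_end}")
    for iso in ISOLATES:
        n = len(truth.planted_snvs[iso])
        ns = sum(s.effect == "nonsynonymous" for s in truth.planted_snvs[iso])
        print(f"{iso}: planted {n} SNVs ({ns} nonsynonymous)")

    base, _ = generate_reference(seed=args.seed + 1, genome_id="prf_genome",
                                 forbid_slippery=True)
    prf_genome, site = plant_prf_site(base, position=3419, seed=args.seed)
    write_fasta([prf_genome], out / "prf_genome.fasta")
    (out / "prf_truth.json").write_text(json.dumps(site.__dict__, indent=1))
    print(f"prf_genome: {site.pattern} at {site.start}, "
          f"hairpin stem {site.stem} / loop {site.loop}")

    leaves = evolve_on_tree(truth.reference, TRUE_TREE, model="JC",
                            seed=args.seed + 2)
    write_fasta(list(leaves.values()), out / "tree_taxa.fasta")
    (out / "true_tree.nwk").write_text(TRUE_TREE + "\n")
    print(f"evolved {len(leaves)} taxa on the known tree")


if __name__ == "__main__":
    main()
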