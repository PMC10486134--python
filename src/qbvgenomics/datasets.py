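"""Packaged reference tables for the Quang Binh virus study system.

These are the published desk-scale inputs the pipeline consumes when no user
data is supplied: the 11-region mature-peptide partition of the QBV
prototype VN180 (reference coordinates), the per-region SNV / nonsynonymous
counts of the three Guizhou isolates against VN180, and the 2021 Guizhou
mosquito collection tallies.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome_io import RegionTable, read_region_table
from .surveillance import CollectionTally

ISOLATES = ("GZ21m081", "GZ21m120", "GZ21m167")


def _path(name: str):
    return resources.files("qbvgenomics.data") / name


def load_vn180_regions() -> RegionTable:
    """The VN180 mature-peptide partition (AC+C 113..520 through NS5
    7523..10189; 10,077 nt = 3,359 codons, stop codon excluded)."""
    with resources.as_file(_path("regions_vn180.tsv")) as p:
        return read_region_table(p, reference_id="NC_012671")


def load_vn180_snv_counts() -> pd.DataFrame:
    """Per-region SNV and nonsynonymous counts of the Guizhou isolates
    against VN180 (columns snv_<isolate>, nonsyn_<isolate>)."""
    with resources.as_file(_path("snv_counts_vn180.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def snv_plant_spec(isolate: str) -> dict[str, tuple[int, int]]:
    """The (synonymous, nonsynonymous) per-region planting spec that
    reproduces one isolate's published counts."""
    df = load_vn180_snv_counts().set_index("region")
    return {
        region: (
            int(row[f"snv_{isolate}"] - row[f"nonsyn_{isolate}"]),
            int(row[f"nonsyn_{isolate}"]),
        )
        for region, row in df.iterrows()
    }


def load_collection_tally(level: str = "genus") -> CollectionTally:
    """The 2021 Guizhou mosquito collection (32,177 females), tallied at
    genus or species level.  Species-level rows do not sum to the total
    (minor taxa were not itemized); pass the whole-collection total as the
    composition denominator for species fractions."""
    with resources.as_file(_path("collection_guizhou_2021.csv")) as p:
        df = pd.read_csv(p)
    df = df[df["level"] == level]
    return CollectionTally(counts=dict(zip(df["species"], df["count"].astype(int))))


COLLECTION_TOTAL = 32177
N_POOLS = 200
N_POSITIVE_POOLS = 3
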