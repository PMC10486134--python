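"""Reading, writing and validation of genome sequences and region tables.

The pipeline works on single-segment positive-sense RNA virus genomes stored
as DNA-alphabet FASTA (U is normalized to T at ingest; the frameshift module
re-displays in RNA).  Region tables describe the mature-peptide partition of
the single polyprotein ORF plus the flanking UTRs, in 1-based inclusive
coordinates of a named reference genome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

# IUPAC nucleotide codes (DNA), including ambiguity codes and gap-free only.
IUPAC_DNA = set("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = set("ACGT")

UTR_KIND = "utr"
MAT_PEPTIDE_KIND = "mat_peptide"


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence (uppercase DNA alphabet)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be nonempty")
        bad = _first_illegal(self.sequence)
        if bad is not None:
            raise ValueError(
                f"illegal character {self.sequence[bad]!r} at position {bad + 1} "
                f"in genome {self.id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice1(self, start: int, end: int) -> str:
        """Subsequence by 1-based inclusive coordinates."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"interval {start}..{end} outside genome {self.id!r}")
        return self.sequence[start - 1 : end]


def _first_illegal(seq: str) -> int | None:
    for i, c in enumerate(seq):
        if c not in IUPAC_DNA:
            return i
    return None


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet."""
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[Genome]:
    """Read a multi-record FASTA file into validated :class:`Genome` objects.

    Sequences are uppercased and U->T normalized.  Raises ``ValueError`` for
    an empty file, a duplicate record id, or a non-IUPAC character (reported
    with its 1-based position).
    """
    path = Path(path)
    genomes: list[Genome] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq))
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        genomes.append(Genome(id=rec.id, sequence=seq, description=desc))
    if not genomes:
        raise ValueError(f"no records in {path}")
    return genomes


def write_fasta(genomes: Sequence[Genome], path: str | Path, width: int = 60) -> Path:
    """Write genomes as FASTA with fixed line width; round-trips through
    :func:`read_fasta` byte-stably for sequence content."""
    if not genomes:
        raise ValueError("cannot write an empty genome list")
    if width < 1:
        raise ValueError("line width must be >= 1")
    path = Path(path)
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description=g.description)
        for g in genomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
    return path


@dataclass(frozen=True)
class Region:
    """One annotated interval (UTR or mature peptide), 1-based inclusive."""

    name: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"region {self.name}: bad interval {self.start}..{self.end}")
        if self.kind not in (UTR_KIND, MAT_PEPTIDE_KIND):
            raise ValueError(f"region {self.name}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class RegionTable:
    """The mature-peptide/UTR partition of a polyprotein genome.

    Mat-peptide regions must be contiguous and non-overlapping; the ORF span
    is the union of the mat-peptide regions, optionally extended past the
    last one by a stop codon (``orf_end``).
    """

    reference_id: str
    regions: list[Region] = field(default_factory=list)
    orf_start: int | None = None
    orf_end: int | None = None
    strict: bool = True  # relaxed for tables transferred through an alignment

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: r.start)
        mats = self.mat_peptides
        if mats:
            for prev, nxt in zip(mats, mats[1:]):
                if nxt.start <= prev.end:
                    raise ValueError(
                        f"mat_peptide regions overlap: {prev.name} "
                        f"({prev.start}..{prev.end}) and {nxt.name} "
                        f"({nxt.start}..{nxt.end})"
                    )
                if self.strict and nxt.start != prev.end + 1:
                    raise ValueError(
                        f"gap between mat_peptide regions {prev.name} (ends {prev.end}) "
                        f"and {nxt.name} (starts {nxt.start})"
                    )
            if self.orf_start is None:
                self.orf_start = mats[0].start
            if self.orf_end is None:
                self.orf_end = mats[-1].end
            if self.strict:
                if self.orf_start != mats[0].start:
                    raise ValueError("orf_start must equal the first mat_peptide start")
                if self.orf_end < mats[-1].end:
                    raise ValueError("orf_end before the last mat_peptide end")
                if (self.orf_end - self.orf_start + 1) % 3 != 0:
                    raise ValueError("ORF span length not divisible by 3")

    @property
    def mat_peptides(self) -> list[Region]:
        return [r for r in self.regions if r.kind == MAT_PEPTIDE_KIND]

    @property
    def utrs(self) -> list[Region]:
        return [r for r in self.regions if r.kind == UTR_KIND]

    def region_of(self, pos: int) -> Region | None:
        for r in self.regions:
            if r.contains(pos):
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [r.name for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "kind": [r.kind for r in self.regions],
            }
        )


def read_region_table(
    path: str | Path, reference_id: str = "", orf_end: int | None = None
) -> RegionTable:
    """Read a region TSV (columns region/start/end/kind) into a validated table.

    ``orf_end`` may extend the ORF past the last mat-peptide (stop codon);
    by default the ORF span is exactly the mat-peptide span.
    """
    df = pd.read_csv(path, sep="\t", comment="#", skip_blank_lines=True)
    required = {"region", "start", "end", "kind"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"region table {path} missing columns {sorted(required - set(df.columns))}"
        )
    regions = [
        Region(name=str(row.region), start=int(row.start), end=int(row.end), kind=str(row.kind))
        for row in df.itertuples()
    ]
    return RegionTable(reference_id=reference_id, regions=regions, orf_end=orf_end)


def write_region_table(table: RegionTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, sep="\t", index=False)
    return path
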