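"""ORF finding, UTR delineation and region transfer through an alignment.

Flavivirus genomes carry a single long ORF encoding one polyprotein, so ORF
finding is a deterministic three-frame forward scan (one ORF per
stop-to-stop interval, anchored at its first ATG); the reverse strand is
ignored.  The reference mature-peptide partition is transferred onto a query
genome through the pairwise alignment's coordinate map, snapping boundaries
that fall in query gaps inward so unaligned bases never inflate a region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genome_io import Genome, Region, RegionTable
from .pairwise_align import PairwiseAlignment

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Orf:
    start: int  # 1-based inclusive, first base of ATG
    end: int  # 1-based inclusive, last base of the stop codon
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_orfs(g: Genome, min_length: int = 300) -> list[Orf]:
    """All forward-strand ORFs (ATG..stop, stop included) of at least
    ``min_length`` nt, one per stop-to-stop interval (the longest, i.e. the
    first ATG), sorted by length descending then start ascending."""
    seq = g.sequence
    n = len(seq)
    orfs: list[Orf] = []
    for frame in range(3):
        atg: int | None = None  # 0-based index of the anchoring ATG
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if atg is not None:
                    orf = Orf(start=atg + 1, end=i + 3)
                    if orf.length >= min_length:
                        orfs.append(orf)
                    atg = None
            elif codon == "ATG" and atg is None:
                atg = i
    return sorted(orfs, key=lambda o: (-o.length, o.start))


def delineate_utrs(g: Genome, orf: Orf) -> dict[str, tuple[int, int] | None]:
    """UTR intervals flanking the ORF (1-based inclusive; None when empty)."""
    if not (1 <= orf.start <= orf.end <= g.length):
        raise ValueError(f"ORF {orf.start}..{orf.end} outside genome {g.id!r}")
    utr5 = (1, orf.start - 1) if orf.start > 1 else None
    utr3 = (orf.end + 1, g.length) if orf.end < g.length else None
    return {"utr5": utr5, "utr3": utr3}


def utr_lengths(g: Genome, orf: Orf) -> dict[str, int]:
    utrs = delineate_utrs(g, orf)
    return {
        k: (v[1] - v[0] + 1 if v is not None else 0) for k, v in utrs.items()
    }


@dataclass
class TransferResult:
    table: RegionTable
    missing: list[str]  # regions entirely deleted in the query


def transfer_regions(table: RegionTable, aln: PairwiseAlignment) -> TransferResult:
    """Map a reference region table onto query coordinates via the alignment.

    A boundary that falls in a query gap snaps inward (start snaps right,
    end snaps left).  Regions with no aligned query base are reported in
    ``missing`` rather than silently dropped.  The transferred table is not
    required to be contiguous (a deletion spanning a boundary opens a gap).
    """
    if table.reference_id and table.reference_id != aln.ref_id:
        raise ValueError(
            f"region table refers to {table.reference_id!r}, "
            f"alignment reference is {aln.ref_id!r}"
        )
    ref_len = len(aln.ungapped_ref())
    ref2qry: list[int | None] = [None] * (ref_len + 1)
    qpos = 0
    rpos = 0
    for cr, cq in zip(aln.aligned_ref, aln.aligned_qry):
        if cq != "-":
            qpos += 1
        if cr != "-":
            rpos += 1
            ref2qry[rpos] = qpos if cq != "-" else None

    def snap(start: int, end: int) -> tuple[int, int] | None:
        s = next((ref2qry[p] for p in range(start, end + 1) if ref2qry[p]), None)
        e = next((ref2qry[p] for p in range(end, start - 1, -1) if ref2qry[p]), None)
        if s is None or e is None or s > e:
            return None
        return s, e

    out: list[Region] = []
    missing: list[str] = []
    for r in table.regions:
        mapped = snap(r.start, r.end)
        if mapped is None:
            missing.append(r.name)
        else:
            out.append(replace(r, start=mapped[0], end=mapped[1]))

    orf_mapped = None
    if table.orf_start is not None and table.orf_end is not None:
        orf_mapped = snap(table.orf_start, table.orf_end)
    new = RegionTable(
        reference_id=aln.qry_id,
        regions=out,
        orf_start=orf_mapped[0] if orf_mapped else None,
        orf_end=orf_mapped[1] if orf_mapped else None,
        strict=False,
    )
    return TransferResult(table=new, missing=missing)
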