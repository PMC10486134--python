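"""SNV extraction and codon-aware effect annotation against a reference.

Variants are called from a global pairwise alignment (substitution columns
only; indels and ambiguity-code columns are excluded).  Each coding SNV is
classified synonymous/nonsynonymous by substituting the alternate base into
the *reference* codon at its codon position — co-occurring substitutions in
the same codon are deliberately not combined (per-variant annotation in the
style of ANNOVAR); such codons are flagged as multi-hit instead.  The codon
frame is the single polyprotein ORF, so regions that split codons (e.g. the
69-nt 2K peptide) are still classified in the correct global frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from ._round import round_half_up
from .genome_io import Genome, RegionTable, UNAMBIGUOUS
from .pairwise_align import PairwiseAlignment

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING = "noncoding"

#: the 12 ordered substitution types, transitions first
SUBSTITUTION_TYPES = [
    "A>G", "G>A", "C>T", "T>C",
    "A>C", "A>T", "C>A", "C>G", "G>C", "G>T", "T>A", "T>G",
]


@dataclass
class SNVRecord:
    """One single-nucleotide substitution in reference coordinates."""

    ref_pos: int
    ref_base: str
    alt_base: str
    sample: str = ""
    region: str | None = None
    codon_index: int | None = None
    codon_pos: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    effect: str | None = None
    multihit: bool = False

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError(f"pos {self.ref_pos}: ref and alt base identical")

    @property
    def substitution(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"


def call_snvs(aln: PairwiseAlignment) -> list[SNVRecord]:
    """Substitution columns of the alignment, sorted by reference position.

    Gap columns and columns where either base is an ambiguity code yield no
    record.
    """
    records: list[SNVRecord] = []
    rpos = 0
    for cr, cq in zip(aln.aligned_ref, aln.aligned_qry):
        if cr != "-":
            rpos += 1
        if cr == "-" or cq == "-":
            continue
        if cr not in UNAMBIGUOUS or cq not in UNAMBIGUOUS:
            continue
        if cr != cq:
            records.append(
                SNVRecord(ref_pos=rpos, ref_base=cr, alt_base=cq, sample=aln.qry_id)
            )
    return records


def _codon_aa(codon: str) -> str:
    return str(Seq(codon).translate())


def classify(
    snvs: Sequence[SNVRecord], ref: Genome, table: RegionTable
) -> list[SNVRecord]:
    """Attach region labels and synonymous/nonsynonymous/noncoding effects.

    Every SNV is evaluated independently against the reference codon; codons
    hit by more than one SNV are additionally flagged ``multihit``.
    """
    orf_start, orf_end = table.orf_start, table.orf_end
    if orf_start is None or orf_end is None:
        raise ValueError("region table does not define an ORF span")
    if orf_end > ref.length:
        raise ValueError("ORF extends past the reference end")

    out: list[SNVRecord] = []
    for snv in sorted(snvs, key=lambda s: s.ref_pos):
        if not (1 <= snv.ref_pos <= ref.length):
            raise ValueError(f"SNV position {snv.ref_pos} outside {ref.id!r}")
        if ref.sequence[snv.ref_pos - 1] != snv.ref_base:
            raise ValueError(
                f"SNV at {snv.ref_pos} claims ref base {snv.ref_base!r} but the "
                f"reference has {ref.sequence[snv.ref_pos - 1]!r}"
            )
        hit = table.region_of(snv.ref_pos)
        if orf_start <= snv.ref_pos <= orf_end:
            offset = snv.ref_pos - orf_start
            codon_index = offset // 3 + 1
            codon_pos = offset % 3 + 1
            cstart = orf_start + 3 * (codon_index - 1)
            ref_codon = ref.sequence[cstart - 1 : cstart + 2]
            alt_codon = (
                ref_codon[: codon_pos - 1] + snv.alt_base + ref_codon[codon_pos:]
            )
            ref_aa = _codon_aa(ref_codon)
            alt_aa = _codon_aa(alt_codon)
            effect = SYNONYMOUS if ref_aa == alt_aa else NONSYNONYMOUS
            region = hit.name if hit else "stop"
            out.append(
                replace(
                    snv,
                    region=region,
                    codon_index=codon_index,
                    codon_pos=codon_pos,
                    ref_codon=ref_codon,
                    alt_codon=alt_codon,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    effect=effect,
                )
            )
        else:
            region = hit.name if hit else ("5UTR" if snv.ref_pos < orf_start else "3UTR")
            out.append(replace(snv, region=region, effect=NONCODING))

    # Flag codons carrying more than one substitution.
    counts: dict[int, int] = {}
    for s in out:
        if s.codon_index is not None:
            counts[s.codon_index] = counts.get(s.codon_index, 0) + 1
    for i, s in enumerate(out):
        if s.codon_index is not None and counts[s.codon_index] > 1:
            out[i] = replace(s, multihit=True)
    return out


def summarize_regions(
    snvs_by_query: Mapping[str, Sequence[SNVRecord]], table: RegionTable
) -> pd.DataFrame:
    """Per-region SNV and nonsynonymous counts per query, with cross-query
    means (half-up, one decimal) and a totals row over the coding regions.

    UTR rows (and any SNV falling in no annotated region) are listed but not
    included in the totals row, which sums the mat-peptide regions only.
    """
    queries = list(snvs_by_query)
    ordered = [r for r in table.regions]
    names = [r.name for r in ordered]
    extra = sorted(
        {s.region for snvs in snvs_by_query.values() for s in snvs}
        - set(names)
        - {None}
    )

    rows = []
    for r in ordered + extra:
        if isinstance(r, str):
            name, start, end, kind = r, None, None, "other"
        else:
            name, start, end, kind = r.name, r.start, r.end, r.kind
        row: dict[str, object] = {"region": name, "start": start, "end": end, "kind": kind}
        snv_counts, ns_counts = [], []
        for q in queries:
            snvs = [s for s in snvs_by_query[q] if s.region == name]
            if any(s.effect is None for s in snvs):
                raise ValueError("summarize_regions requires classified SNVs")
            n = len(snvs)
            ns = sum(1 for s in snvs if s.effect == NONSYNONYMOUS)
            row[f"snv_{q}"] = n
            row[f"nonsyn_{q}"] = ns
            snv_counts.append(n)
            ns_counts.append(ns)
        row["mean_snv"] = round_half_up(sum(snv_counts) / len(queries), 1)
        row["mean_nonsyn"] = round_half_up(sum(ns_counts) / len(queries), 1)
        rows.append(row)

    df = pd.DataFrame(rows)
    coding = df[df["kind"] == "mat_peptide"]
    total: dict[str, object] = {"region": "total", "start": None, "end": None, "kind": "total"}
    for q in queries:
        total[f"snv_{q}"] = int(coding[f"snv_{q}"].sum())
        total[f"nonsyn_{q}"] = int(coding[f"nonsyn_{q}"].sum())
    total["mean_snv"] = round_half_up(
        sum(int(coding[f"snv_{q}"].sum()) for q in queries) / len(queries), 1
    )
    total["mean_nonsyn"] = round_half_up(
        sum(int(coding[f"nonsyn_{q}"].sum()) for q in queries) / len(queries), 1
    )
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


@dataclass
class SubstitutionSpectrum:
    counts: dict[str, int]
    proportions: dict[str, float] | None  # None when no SNV passes the filters

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def spectrum(
    snvs: Iterable[SNVRecord],
    region: str | set[str] | None = None,
    effect: str | None = None,
) -> SubstitutionSpectrum:
    """Counts and percentages of the 12 substitution types among SNVs
    passing the region/effect filters."""
    regions = {region} if isinstance(region, str) else region
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    for s in snvs:
        if regions is not None and s.region not in regions:
            continue
        if effect is not None and s.effect != effect:
            continue
        counts[s.substitution] += 1
    total = sum(counts.values())
    props = (
        {t: round_half_up(100.0 * c / total, 1) for t, c in counts.items()}
        if total > 0
        else None
    )
    return SubstitutionSpectrum(counts=counts, proportions=props)


# --- VCF 4.2 output -------------------------------------------------------

_VCF_INFO = (
    '##INFO=<ID=REGION,Number=1,Type=String,Description="Annotated region">\n'
    '##INFO=<ID=EFFECT,Number=1,Type=String,Description="SNV effect class">\n'
    '##INFO=<ID=CODON,Number=1,Type=String,Description="ref_codon>alt_codon">\n'
    '##INFO=<ID=AA,Number=1,Type=String,Description="ref_aa>alt_aa">\n'
    '##INFO=<ID=CODON_INDEX,Number=1,Type=Integer,Description="Codon number in ORF">\n'
    '##INFO=<ID=CODON_POS,Number=1,Type=Integer,Description="Position in codon (1-3)">\n'
    '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Query genome id">\n'
    '##INFO=<ID=MULTIHIT,Number=0,Type=Flag,Description="Codon hit by >1 SNV">\n'
)


def write_vcf(snvs: Sequence[SNVRecord], ref: Genome, path: str | Path) -> Path:
    """Write classified SNVs as a VCF 4.2 file (one data line per record)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.id},length={ref.length}>\n")
        fh.write(_VCF_INFO)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snvs, key=lambda s: s.ref_pos):
            info = [f"REGION={s.region}", f"EFFECT={s.effect}"]
            if s.codon_index is not None:
                info += [
                    f"CODON={s.ref_codon}>{s.alt_codon}",
                    f"AA={s.ref_aa}>{s.alt_aa}",
                    f"CODON_INDEX={s.codon_index}",
                    f"CODON_POS={s.codon_pos}",
                ]
            if s.sample:
                info.append(f"SAMPLE={s.sample}")
            if s.multihit:
                info.append("MULTIHIT")
            fh.write(
                f"{ref.id}\t{s.ref_pos}\t.\t{s.ref_base}\t{s.alt_base}\t.\t.\t"
                + ";".join(info)
                + "\n"
            )
    return path


def read_vcf(path: str | Path) -> list[SNVRecord]:
    """Parse a VCF written by :func:`write_vcf` back into records."""
    out: list[SNVRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, _id, refb, altb, _q, _f, info = line.rstrip("\n").split("\t")
            kv: dict[str, str] = {}
            flags: set[str] = set()
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k] = v
                else:
                    flags.add(item)
            codon = kv.get("CODON", ">").split(">")
            aa = kv.get("AA", ">").split(">")
            out.append(
                SNVRecord(
                    ref_pos=int(pos),
                    ref_base=refb,
                    alt_base=altb,
                    sample=kv.get("SAMPLE", ""),
                    region=kv.get("REGION"),
                    codon_index=int(kv["CODON_INDEX"]) if "CODON_INDEX" in kv else None,
                    codon_pos=int(kv["CODON_POS"]) if "CODON_POS" in kv else None,
                    ref_codon=codon[0] or None,
                    alt_codon=codon[1] or None,
                    ref_aa=aa[0] or None,
                    alt_aa=aa[1] or None,
                    effect=kv.get("EFFECT"),
                    multihit="MULTIHIT" in flags,
                )
            )
    return out
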