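"""Similarity profiling: per-region identities, sliding-window tracks and
the all-pairs identity matrix over coding regions / translated polyproteins.

All identities share the single definition in :func:`pairwise_align.identity`
(blastn-style: internal gap columns count against identity, terminal
overhangs and ambiguity columns are excluded).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._round import round_half_up
from .annotation import find_orfs
from .genome_io import Genome, RegionTable
from .pairwise_align import AlignParams, PairwiseAlignment, global_align, identity, translate


def region_similarity(
    alignments: Mapping[str, PairwiseAlignment], table: RegionTable
) -> pd.DataFrame:
    """Percent identity per annotated region for each query alignment, with
    the cross-query mean (half-up, one decimal)."""
    queries = list(alignments)
    rows = []
    for r in table.regions:
        row: dict[str, object] = {
            "region": r.name, "start": r.start, "end": r.end, "kind": r.kind,
        }
        vals = []
        for q in queries:
            v = identity(alignments[q], ref_interval=(r.start, r.end), rounded=False)
            row[f"identity_{q}"] = round_half_up(v, 1)
            vals.append(v)
        row["mean"] = round_half_up(sum(vals) / len(vals), 1)
        rows.append(row)
    return pd.DataFrame(rows)


def window_identity(
    aln: PairwiseAlignment, window: int = 500, step: int = 250
) -> pd.DataFrame:
    """Sliding-window identity track over the reference span.

    Windows tile the reference; the final window may be shorter and is
    flagged ``partial``.  A window wider than the reference yields a single
    full-span window.
    """
    if not (1 <= step <= window):
        raise ValueError("need window >= step >= 1")
    ref_len = len(aln.ungapped_ref())
    window = min(window, ref_len)
    rows = []
    start = 1
    while start <= ref_len:
        end = min(start + window - 1, ref_len)
        rows.append(
            {
                "ref_start": start,
                "ref_end": end,
                "identity": identity(aln, ref_interval=(start, end)),
                "partial": end - start + 1 < window,
            }
        )
        if end == ref_len:
            break
        start += step
    return pd.DataFrame(rows)


def identity_matrix(
    genomes: Sequence[Genome],
    mode: str = "nt_cds",
    params: AlignParams = AlignParams(),
    min_orf_length: int = 300,
) -> pd.DataFrame:
    """Symmetric all-pairs identity matrix over coding sequences.

    ``nt_cds`` aligns the nucleotide CDS of each genome pair; ``aa`` aligns
    the translated polyproteins.  Genomes without an ORF of at least
    ``min_orf_length`` nt are excluded with a warning column left out.
    The upper and lower triangles use the same code path, so the matrix is
    exactly symmetric with a 100.0 diagonal.
    """
    if mode not in ("nt_cds", "aa"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")

    seqs: dict[str, str] = {}
    for g in genomes:
        orfs = find_orfs(g, min_length=min_orf_length)
        if not orfs:
            import warnings

            warnings.warn(f"genome {g.id!r} has no ORF >= {min_orf_length} nt; excluded")
            continue
        cds = g.slice1(orfs[0].start, orfs[0].end)
        seqs[g.id] = cds if mode == "nt_cds" else translate(cds)

    labels = list(seqs)
    mat = pd.DataFrame(100.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if mode == "aa":
                pct = _aa_identity(seqs[a], seqs[b], params)
            else:
                aln = global_align(seqs[a], seqs[b], params)
                pct = identity(aln)
            mat.loc[a, b] = pct
            mat.loc[b, a] = pct
    return mat


def _aa_identity(a: str, b: str, params: AlignParams) -> float:
    """Identity of two protein sequences via the same global DP (match /
    mismatch scoring on residues)."""
    aln = global_align(a, b, params)
    L = len(aln.aligned_ref)
    i = 0
    while i < L and (aln.aligned_ref[i] == "-" or aln.aligned_qry[i] == "-"):
        i += 1
    j = L
    while j > i and (aln.aligned_ref[j - 1] == "-" or aln.aligned_qry[j - 1] == "-"):
        j -= 1
    cols = [(aln.aligned_ref[k], aln.aligned_qry[k]) for k in range(i, j)]
    if not cols:
        raise ValueError("no comparable columns")
    matches = sum(1 for x, y in cols if x == y)
    return round_half_up(100.0 * matches / len(cols), 1)


def export_tracks(
    windows: pd.DataFrame,
    regions: pd.DataFrame,
    path_prefix: str | Path,
    ref_id: str = "ref",
) -> dict[str, Path]:
    """Write the window track as BED (0-based half-open) plus TSVs for the
    window and region summaries."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed = prefix.with_suffix(".windows.bed")
    with open(bed, "w") as fh:
        for row in windows.itertuples():
            fh.write(
                f"{ref_id}\t{row.ref_start - 1}\t{row.ref_end}\t"
                f"identity\t{row.identity}\n"
            )
    wtsv = prefix.with_suffix(".windows.tsv")
    windows.to_csv(wtsv, sep="\t", index=False)
    rtsv = prefix.with_suffix(".regions.tsv")
    regions.to_csv(rtsv, sep="\t", index=False)
    return {"bed": bed, "windows_tsv": wtsv, "regions_tsv": rtsv}
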