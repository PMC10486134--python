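"""Global pairwise nucleotide alignment with affine gaps, banded for speed.

Genomes compared here are >=84% identical, so a band of a few hundred
diagonals around the main diagonal always contains the optimal path; the
banded dynamic program is exact within the band and identical to full
Needleman-Wunsch/Gotoh whenever the band covers the optimum.  Setting
``band_width=None`` runs the full DP (used as its own oracle on small
instances).

Scoring convention: the first base of a gap costs ``gap_open``, each further
base ``gap_extend`` (both negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .genome_io import Genome, UNAMBIGUOUS
from ._round import round_half_up

NEG = -1e18  # effectively -infinity for the DP


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    band_width: Optional[int] = 600


@dataclass
class PairwiseAlignment:
    """A global alignment of a query genome against a reference."""

    ref_id: str
    qry_id: str
    aligned_ref: str
    aligned_qry: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_qry):
            raise ValueError("aligned strings must have equal length")
        for a, b in zip(self.aligned_ref, self.aligned_qry):
            if a == "-" and b == "-":
                raise ValueError("column gapped in both sequences")

    @property
    def ref_coord_map(self) -> list[int | None]:
        """Per-column 1-based reference position (None in insertion columns)."""
        out: list[int | None] = []
        pos = 0
        for c in self.aligned_ref:
            if c == "-":
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    @property
    def qry_coord_map(self) -> list[int | None]:
        out: list[int | None] = []
        pos = 0
        for c in self.aligned_qry:
            if c == "-":
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    def ungapped_ref(self) -> str:
        return self.aligned_ref.replace("-", "")

    def ungapped_qry(self) -> str:
        return self.aligned_qry.replace("-", "")


class BandTooNarrowError(ValueError):
    pass


def _band_limits(m: int, n: int, band_width: Optional[int]) -> tuple[int, int]:
    """Diagonal offsets d = j - i kept in the band; must include 0 and n-m."""
    if band_width is None:
        return -m, n
    delta = n - m
    extra = (band_width - abs(delta)) // 2
    if extra < 0:
        raise BandTooNarrowError(
            f"band_width={band_width} cannot connect sequences differing by "
            f"{abs(delta)} nt; widen the band to at least {abs(delta)}"
        )
    return min(0, delta) - extra, max(0, delta) + extra


def global_align(
    ref: Genome | str, qry: Genome | str, params: AlignParams = AlignParams()
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment within the band (Gotoh three-state
    DP, vectorized row by row).  Deterministic: traceback ties prefer
    diagonal > up (gap in query) > left (gap in reference)."""
    ref_id = ref.id if isinstance(ref, Genome) else "ref"
    qry_id = qry.id if isinstance(qry, Genome) else "qry"
    rseq = ref.sequence if isinstance(ref, Genome) else ref
    qseq = qry.sequence if isinstance(qry, Genome) else qry
    if not rseq or not qseq:
        raise ValueError("cannot align empty sequences")

    m, n = len(rseq), len(qseq)
    dmin, dmax = _band_limits(m, n, params.band_width)
    W = dmax - dmin + 1
    go, ge = params.gap_open, params.gap_extend

    r = np.frombuffer(rseq.encode(), dtype=np.uint8)
    q = np.frombuffer(qseq.encode(), dtype=np.uint8)

    # Row 0 initialization (i = 0): only leading gaps in the reference.
    j0 = np.arange(W) + dmin  # query positions j at row 0
    M = np.full(W, NEG)
    X = np.full(W, NEG)
    Y = np.full(W, NEG)
    valid0 = (j0 >= 0) & (j0 <= n)
    if dmin <= 0 <= dmax:
        M[-dmin] = 0.0
    with np.errstate(invalid="ignore"):
        Y[valid0 & (j0 >= 1)] = go + (j0[valid0 & (j0 >= 1)] - 1) * ge

    # Pointer codes: 0 = from M, 1 = from X, 2 = from Y.
    ptrM = np.zeros((m + 1, W), dtype=np.int8)
    ptrX = np.zeros((m + 1, W), dtype=np.int8)
    ptrY = np.full((m + 1, W), 2, dtype=np.int8)
    ptrY[0, :] = 2
    if dmin <= 1 <= dmax:
        ptrY[0, 1 - dmin] = 0  # first query gap opens from the origin

    idx_arange = np.arange(W)
    for i in range(1, m + 1):
        j = i + dmin + idx_arange  # query position per band slot
        inb = (j >= 0) & (j <= n)
        jpos = (j >= 1) & (j <= n)

        # Diagonal predecessors (i-1, j-1) sit at the same band slot.
        diag_best = np.maximum(np.maximum(M, X), Y)
        diag_ptr = np.where(M >= np.maximum(X, Y), 0, np.where(X >= Y, 1, 2)).astype(np.int8)
        sub = np.full(W, params.mismatch)
        jq = np.clip(j - 1, 0, n - 1)
        sub[r[i - 1] == q[jq]] = params.match
        newM = np.where(jpos, diag_best + sub, NEG)
        ptrM[i] = diag_ptr

        # Vertical predecessors (i-1, j) sit one slot to the right.
        upM = np.concatenate([M[1:], [NEG]])
        upX = np.concatenate([X[1:], [NEG]])
        upY = np.concatenate([Y[1:], [NEG]])
        candM, candX, candY = upM + go, upX + ge, upY + go
        newX = np.where(inb, np.maximum(np.maximum(candM, candX), candY), NEG)
        ptrX[i] = np.where(candM >= np.maximum(candX, candY), 0, np.where(candX >= candY, 1, 2))

        # Horizontal moves within the row via a running-max scan:
        # Y[t] = max_{k<t} (B[k] + go + (t-1-k) ge) with B = max(M, X).
        B = np.maximum(newM, newX)
        C = B + go - ge * (idx_arange + 1)
        run = np.maximum.accumulate(C)
        newY = np.full(W, NEG)
        newY[1:] = run[:-1] + ge * idx_arange[1:]
        newY = np.where(jpos, newY, NEG)
        open_sc = np.full(W, NEG)
        open_sc[1:] = B[:-1] + go
        from_open = open_sc >= newY - 1e-9
        prefer_m = np.concatenate([[True], newM[:-1] >= newX[:-1]])
        ptrY[i] = np.where(from_open, np.where(prefer_m, 0, 1), 2)

        M, X, Y = newM, newX, newY
        # Slot for j = 0 (leading query gap) must stay reachable:
        if dmin + i <= 0:
            k0 = -dmin - i
            M[k0] = NEG
            Y[k0] = NEG
            X[k0] = go + (i - 1) * ge
            ptrX[i, k0] = 1 if i > 1 else 0

        M[~inb] = NEG
        X[~inb] = NEG
        Y[~inb] = NEG

    end_idx = n - m - dmin
    if not (0 <= end_idx < W):
        raise BandTooNarrowError("band does not reach the terminal corner; widen it")
    finals = (M[end_idx], X[end_idx], Y[end_idx])
    state = int(np.argmax([finals[0] + 1e-9, finals[1] + 5e-10, finals[2]]))
    score = float(finals[state])
    if score <= NEG / 2:
        raise BandTooNarrowError("no path through the band; widen it")

    # Traceback.
    cols_r: list[str] = []
    cols_q: list[str] = []
    i, idx = m, end_idx
    while True:
        j = i + dmin + idx
        if i == 0 and j == 0:
            break
        if i == 0:
            cols_r.append("-")
            cols_q.append(qseq[j - 1])
            idx -= 1
            continue
        if j == 0:
            cols_r.append(rseq[i - 1])
            cols_q.append("-")
            i -= 1
            idx += 1
            continue
        if state == 0:
            cols_r.append(rseq[i - 1])
            cols_q.append(qseq[j - 1])
            state = int(ptrM[i, idx])
            i -= 1
        elif state == 1:
            cols_r.append(rseq[i - 1])
            cols_q.append("-")
            state = int(ptrX[i, idx])
            i -= 1
            idx += 1
        else:
            cols_r.append("-")
            cols_q.append(qseq[j - 1])
            state = int(ptrY[i, idx])
            idx -= 1

    aln = PairwiseAlignment(
        ref_id=ref_id,
        qry_id=qry_id,
        aligned_ref="".join(reversed(cols_r)),
        aligned_qry="".join(reversed(cols_q)),
        score=score,
    )
    assert aln.ungapped_ref() == rseq and aln.ungapped_qry() == qseq
    return aln


def _core_span(aln: PairwiseAlignment) -> tuple[int, int]:
    """Column range [a, b) excluding terminal overhangs (leading/trailing
    gap runs in either sequence)."""
    L = len(aln.aligned_ref)
    a = 0
    while a < L and (aln.aligned_ref[a] == "-" or aln.aligned_qry[a] == "-"):
        a += 1
    b = L
    while b > a and (aln.aligned_ref[b - 1] == "-" or aln.aligned_qry[b - 1] == "-"):
        b -= 1
    return a, b


def identity(
    aln: PairwiseAlignment,
    ref_interval: tuple[int, int] | None = None,
    rounded: bool = True,
) -> float:
    """Percent identity over the aligned core (blastn-style).

    The denominator counts every column whose reference position falls in
    ``ref_interval`` (insertion columns inherit the position of the last
    reference base to their left), including internal gap columns; columns
    carrying an ambiguity code in either sequence are excluded; terminal
    overhangs are excluded.
    """
    if ref_interval is not None:
        lo, hi = ref_interval
        if lo > hi:
            raise ValueError(f"empty reference interval {lo}..{hi}")
    a, b = _core_span(aln)
    coords = aln.ref_coord_map
    anchor = None
    matches = 0
    denom = 0
    for col in range(len(coords)):
        pos = coords[col]
        if pos is not None:
            anchor = pos
        if not (a <= col < b):
            continue
        eff = pos if pos is not None else anchor
        if ref_interval is not None and (eff is None or not (lo <= eff <= hi)):
            continue
        x, y = aln.aligned_ref[col], aln.aligned_qry[col]
        if (x != "-" and x not in UNAMBIGUOUS) or (y != "-" and y not in UNAMBIGUOUS):
            continue  # ambiguity codes carry no identity information
        denom += 1
        if x == y:
            matches += 1
    if denom == 0:
        raise ValueError("no comparable columns in the requested interval")
    pct = 100.0 * matches / denom
    return round_half_up(pct, 1) if rounded else pct


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide sequence with the standard code.

    A terminal stop codon is dropped; internal stops are rendered ``*`` with
    a warning; codons that do not resolve to a single residue give ``X``.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    aa = str(Seq(seq).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        warnings.warn("internal stop codon in translation", stacklevel=2)
    return aa


def write_alignment_fasta(aln: PairwiseAlignment, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{aln.ref_id}\n{aln.aligned_ref}\n>{aln.qry_id}\n{aln.aligned_qry}\n")
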