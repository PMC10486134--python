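"""Detection of candidate -1 programmed ribosomal frameshift (PRF) sites.

Insect-specific flaviviruses express the overlapping *fifo* gene in the
NS2A-NS2B region through -1 ribosomal frameshifting at a slippery
heptanucleotide (canonically G_GAU_UUC), stimulated by a downstream RNA
stem-loop.  This module scans for the five slippery heptamer patterns
reported in insect flaviviruses, folds the 150 nt downstream of each match
by nested base-pair maximization (Watson-Crick + GU wobble, hairpin loops of
at least ``min_loop``), and verifies a hairpin of sufficient stem length
near the slippery site.

The folding objective is maximum pair cardinality (Nussinov-style dynamic
programming with deterministic traceback), not thermodynamic free energy:
the question asked of the fold — is there a stem-loop just downstream? — is
robust to the objective, and a thermodynamic folder can be plugged in via
the ``fold_fn`` hook of :func:`detect_prf` by anyone wanting MFE structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import Genome, RegionTable

DEFAULT_PATTERNS = ("GGAUUUC", "GGAUUUU", "GUUUUUU", "UUUUUUU", "UUUUUUC")
RNA_ALPHABET = set("ACGU")
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class FoldResult:
    """A nested (pseudoknot-free) pairing of a sequence window."""

    window: str  # RNA alphabet
    pairing: list[tuple[int, int]]  # 1-based (i, j), i < j
    dot_bracket: str

    @property
    def pair_count(self) -> int:
        return len(self.pairing)


@dataclass
class SlipperySite:
    pattern: str  # RNA alphabet heptamer
    start: int  # 1-based genome coordinate of the heptamer's first base
    region: str | None
    downstream_seq: str  # RNA, up to 150 nt after the heptamer
    structure: str
    stem_loop_found: bool
    stem_length: int
    loop_length: int
    truncated_window: bool = False


def scan_slippery(
    g: Genome,
    patterns: Sequence[str] = DEFAULT_PATTERNS,
    search_interval: tuple[int, int] | None = None,
) -> list[tuple[str, int]]:
    """All exact occurrences (T treated as U) of the slippery patterns,
    overlapping matches included, as (pattern, 1-based start) sorted by
    start."""
    if not patterns:
        raise ValueError("need at least one pattern")
    for p in patterns:
        if len(p) != 7 or set(p) - RNA_ALPHABET:
            raise ValueError(f"pattern {p!r} is not a 7-nt RNA string")
    seq = g.sequence
    lo, hi = (1, g.length) if search_interval is None else search_interval
    hits: list[tuple[str, int]] = []
    for p in patterns:
        target = to_dna(p)
        start = lo - 1
        while True:
            idx = seq.find(target, start, hi)
            if idx == -1:
                break
            hits.append((p, idx + 1))
            start = idx + 1
    return sorted(hits, key=lambda h: (h[1], h[0]))


def _can_pair(x: str, y: str) -> bool:
    return (x, y) in _PAIRS


def fold(
    window: str, min_loop: int = 3, allow_GU: bool = True, objective: str = "pairs"
) -> FoldResult:
    """Optimal nested pairing by Nussinov-style dynamic programming.

    Hairpin loops are at least ``min_loop`` unpaired bases (j - i > min_loop
    for any pair i,j).  With ``objective="pairs"`` (default) the structure
    maximizes the number of pairs, using the stacked-pair count only to
    break ties; ``objective="stacks"`` maximizes stacked pairs first (pairs
    second), which favors contiguous helices the way a thermodynamic folder
    does and is what the frameshift detector uses for stem-loop
    verification.  Traceback is deterministic: pairing the interval ends is
    preferred over bifurcation; bifurcations split at the smallest point.
    """
    rna = to_rna(window)
    n = len(rna)
    if n < min_loop + 2:
        return FoldResult(window=rna, pairing=[], dot_bracket="." * n)
    pairs = _PAIRS if allow_GU else {p for p in _PAIRS if set(p) != {"G", "U"}}
    if objective == "pairs":
        pair_unit, stack_unit = 1 << 10, 1
    elif objective == "stacks":
        pair_unit, stack_unit = 1, 1 << 10
    else:
        raise ValueError(f"unknown objective {objective!r}")

    NEG = np.int32(-(1 << 28))
    # free[i][j]: best packed score; paired[i][j]: ditto with (i,j) paired
    free = np.zeros((n, n), dtype=np.int32)
    paired = np.full((n, n), NEG, dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if (rna[i], rna[j]) in pairs:
                if i + 1 <= j - 1:
                    inner = free[i + 1][j - 1]
                    if paired[i + 1][j - 1] + stack_unit > inner:  # stack bonus
                        inner = paired[i + 1][j - 1] + stack_unit
                else:
                    inner = 0
                paired[i][j] = inner + pair_unit
            best = free[i][j - 1]  # j unpaired
            if paired[i][j] > best:
                best = paired[i][j]
            ks = np.arange(i, j)
            cand = free[i, i:j] + free[ks + 1, j]
            cbest = np.int32(cand.max())
            if cbest > best:
                best = cbest
            free[i][j] = best

    pairing: list[tuple[int, int]] = []
    stack = [(0, n - 1, "free")]
    while stack:
        i, j, mode = stack.pop()
        if i >= j:
            continue
        if mode == "paired":
            pairing.append((i + 1, j + 1))
            if i + 1 <= j - 1:
                want = paired[i][j] - pair_unit
                if paired[i + 1][j - 1] + stack_unit == want:
                    stack.append((i + 1, j - 1, "paired"))
                else:
                    stack.append((i + 1, j - 1, "free"))
            continue
        if free[i][j] == 0:
            continue
        if paired[i][j] == free[i][j]:
            stack.append((i, j, "paired"))
            continue
        if free[i][j] == free[i][j - 1]:
            stack.append((i, j - 1, "free"))
            continue
        for k in range(i, j):
            if free[i][k] + free[k + 1][j] == free[i][j]:
                stack.append((i, k, "free"))
                stack.append((k + 1, j, "free"))
                break

    pairing.sort()
    db = ["."] * n
    for i, j in pairing:
        db[i - 1] = "("
        db[j - 1] = ")"
    return FoldResult(window=rna, pairing=pairing, dot_bracket="".join(db))


def stem_loop_check(
    fr: FoldResult,
    min_stem: int = 4,
    loop_range: tuple[int, int] = (3, 10),
    search_prefix: int = 60,
) -> dict:
    """Look for a hairpin: a helix of >= ``min_stem`` stacked pairs (single
    bulges allowed between stacks) closing a terminal loop within
    ``loop_range``, with the helix 5' end inside the first ``search_prefix``
    nt of the window.

    Returns found/stem_length/loop_length/apex; when several hairpins
    qualify, the longest stem (then the most 5') is reported.
    """
    pairset = set(fr.pairing)
    lo, hi = loop_range

    # hairpin-closing pairs: no other pair nested strictly inside
    candidates = []
    for (i, j) in fr.pairing:
        if any(i < a and b < j for (a, b) in fr.pairing if (a, b) != (i, j)):
            continue
        candidates.append((i, j))

    best: dict | None = None
    for (i, j) in candidates:
        loop_len = j - i - 1
        stem = 1
        a, b = i, j
        while True:
            for da, db in ((1, 1), (2, 1), (1, 2)):  # stack, 5' bulge, 3' bulge
                if (a - da, b + db) in pairset:
                    a, b = a - da, b + db
                    stem += 1
                    break
            else:
                break
        ok = stem >= min_stem and lo <= loop_len <= hi and a <= search_prefix
        cand = {
            "found": ok,
            "stem_length": stem,
            "loop_length": loop_len,
            "apex": (i + j) // 2,
            "helix_start": a,
        }
        # the functional stem-loop sits just downstream of the slippery site,
        # so the most 5' qualifying hairpin wins; longer stems break ties
        if best is None:
            best = cand
        else:
            better = (cand["found"], -cand["helix_start"], cand["stem_length"]) > (
                best["found"], -best["helix_start"], best["stem_length"]
            )
            if better:
                best = cand
    if best is None:
        return {"found": False, "stem_length": 0, "loop_length": 0, "apex": None,
                "helix_start": None}
    return best


def detect_prf(
    g: Genome,
    table: Optional[RegionTable] = None,
    window: int = 150,
    patterns: Sequence[str] = DEFAULT_PATTERNS,
    search_interval: tuple[int, int] | None = None,
    min_stem: int = 4,
    loop_range: tuple[int, int] = (3, 10),
    search_prefix: int = 60,
    min_loop: int = 3,
    fold_fn: Callable[[str], FoldResult] | None = None,
) -> list[SlipperySite]:
    """Scan for slippery heptamers and verify each by folding the ``window``
    nt downstream (3' of the heptamer's last base).

    All matches are reported; ``stem_loop_found`` marks the verified ones.
    Matches whose downstream window is cut short by the genome end are
    flagged ``truncated_window``.
    """
    folder = fold_fn or (lambda w: fold(w, min_loop=min_loop, objective="stacks"))
    sites: list[SlipperySite] = []
    for pattern, start in scan_slippery(g, patterns, search_interval):
        assert g.slice1(start, start + 6) == to_dna(pattern)
        ds_start = start + 7
        ds_end = min(g.length, ds_start + window - 1)
        downstream = g.sequence[ds_start - 1 : ds_end] if ds_start <= g.length else ""
        truncated = len(downstream) < window
        fr = folder(to_rna(downstream))
        check = stem_loop_check(fr, min_stem, loop_range, search_prefix)
        region = table.region_of(start).name if table and table.region_of(start) else None
        sites.append(
            SlipperySite(
                pattern=pattern,
                start=start,
                region=region,
                downstream_seq=fr.window,
                structure=fr.dot_bracket,
                stem_loop_found=bool(check["found"]),
                stem_length=int(check["stem_length"]),
                loop_length=int(check["loop_length"]),
                truncated_window=truncated,
            )
        )
    return sites


def sites_table(sites: Sequence[SlipperySite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pattern": [s.pattern for s in sites],
            "start": [s.start for s in sites],
            "region": [s.region for s in sites],
            "stem_loop_found": [s.stem_loop_found for s in sites],
            "stem_length": [s.stem_length for s in sites],
            "loop_length": [s.loop_length for s in sites],
            "truncated_window": [s.truncated_window for s in sites],
        }
    )


def write_sites(sites: Sequence[SlipperySite], path: str | Path) -> Path:
    path = Path(path)
    sites_table(sites).to_csv(path, sep="\t", index=False)
    with open(path.with_suffix(".structures.txt"), "w") as fh:
        for s in sites:
            fh.write(f"> {s.pattern} @ {s.start} region={s.region}\n")
            fh.write(s.downstream_seq + "\n")
            fh.write(s.structure + "\n")
    return path
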