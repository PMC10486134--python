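"""Independent reference implementations used only to check the package.

Each oracle is deliberately written as a direct, slow transcription of the
underlying definition (full DP, exhaustive enumeration, closed forms) and
shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

NEG = float("-inf")


# --- full Needleman-Wunsch/Gotoh over all cells (no banding) --------------


def full_affine_score(a: str, b: str, match=1.0, mismatch=-1.0, go=-4.0, ge=-1.0) -> float:
    """Plain three-state affine-gap global alignment score, O(nm) loops."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0][j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go)
            Y[i][j] = max(M[i][j - 1] + go, X[i][j - 1] + go, Y[i][j - 1] + ge)
    return max(M[n][m], X[n][m], Y[n][m])


# --- exhaustive nested-structure enumeration ------------------------------

_RNA_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def max_pairs_exhaustive(rna: str, min_loop: int = 3) -> int:
    """Maximum pairs over all nested structures, by explicit recursion over
    the first position (paired with each legal partner, or unpaired)."""

    def rec(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (rna[i], rna[k]) in _RNA_PAIRS:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(rna) - 1)


# --- standard genetic code, hand-transcribed ------------------------------

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def codon_effect(ref_codon: str, pos: int, alt: str) -> str:
    """Effect of substituting ``alt`` at codon position ``pos`` (1-3)."""
    alt_codon = ref_codon[: pos - 1] + alt + ref_codon[pos:]
    return (
        "synonymous"
        if CODON_TABLE[ref_codon] == CODON_TABLE[alt_codon]
        else "nonsynonymous"
    )


# --- exhaustive unrooted topology search ----------------------------------


def all_unrooted_topologies(labels: list[str]):
    """All unrooted binary topologies as frozensets of nontrivial splits
    (canonical side: the one not containing labels[0])."""
    if len(labels) < 4:
        yield frozenset()
        return

    # represent a tree as an edge list; grow by inserting each taxon on every edge
    def grow(edges: list[tuple], nxt: int, labels: list[str]):
        if nxt == len(labels):
            yield edges
            return
        for e_idx in range(len(edges)):
            u, v = edges[e_idx]
            new_internal = ("i", nxt, e_idx)
            new_edges = (
                edges[:e_idx]
                + edges[e_idx + 1 :]
                + [(u, new_internal), (new_internal, v), (new_internal, labels[nxt])]
            )
            yield from grow(new_edges, nxt + 1, labels)

    start = [(labels[0], ("i", 0, 0)), (("i", 0, 0), labels[1]), (("i", 0, 0), labels[2])]
    for edges in grow(start, 3, labels):
        yield edges


def topology_splits(edges, labels: list[str]) -> frozenset:
    """Nontrivial splits of an edge-list topology."""
    from collections import defaultdict

    adj = defaultdict(set)
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    labelset = set(labels)
    splits = set()
    for u, v in edges:
        # leaves on v's side when edge (u, v) removed
        seen = {u, v}
        stackk = [v]
        side = set()
        while stackk:
            x = stackk.pop()
            if isinstance(x, str):
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stackk.append(y)
        if labels[0] in side:
            side = labelset - side
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(frozenset(side))
    return frozenset(splits)


def path_lengths_fit(edges, labels: list[str], D) -> float:
    """Least-squares residual of fitting branch lengths to pairwise
    distances on a fixed topology (unconstrained lstsq)."""
    import numpy as np
    from collections import defaultdict

    adj = defaultdict(list)
    edge_index = {tuple(sorted(map(str, e))): i for i, e in enumerate(edges)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)

    def path(a, b):
        # BFS for the node path, return edge indicator vector
        import collections

        prev = {a: None}
        qq = collections.deque([a])
        while qq:
            x = qq.popleft()
            if x == b:
                break
            for y in adj[x]:
                if y not in prev:
                    prev[y] = x
                    qq.append(y)
        vec = [0.0] * len(edges)
        x = b
        while prev[x] is not None:
            vec[edge_index[tuple(sorted(map(str, (x, prev[x]))))]] = 1.0
            x = prev[x]
        return vec

    import numpy as np

    rows, y = [], []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            rows.append(path(a, labels[j]))
            y.append(D[i][j])
    A = np.array(rows)
    yv = np.array(y)
    x, *_ = np.linalg.lstsq(A, yv, rcond=None)
    return float(((A @ x - yv) ** 2).sum())


def best_topology_exhaustive(labels: list[str], D) -> frozenset:
    """The topology (as split set) with the smallest least-squares residual."""
    best, best_res = None, math.inf
    seen = set()
    for edges in all_unrooted_topologies(labels):
        splits = topology_splits(edges, labels)
        if splits in seen:
            continue
        seen.add(splits)
        res = path_lengths_fit(edges, labels, D)
        if res < best_res - 1e-12:
            best, best_res = splits, res
    return best


# --- TN93 closed form, transcribed directly from the published equations --


def tn93_reference(a: str, b: str, gamma_shape: float | None = None) -> float:
    cols = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    n = len(cols)
    cnt = {c: 0 for c in "ACGT"}
    P1 = P2 = Q = 0
    for x, y in cols:
        cnt[x] += 1
        cnt[y] += 1
        if x != y:
            if {x, y} == {"A", "G"}:
                P1 += 1
            elif {x, y} == {"C", "T"}:
                P2 += 1
            else:
                Q += 1
    gA, gC, gG, gT = (cnt[c] / (2 * n) for c in "ACGT")
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = P1 / n, P2 / n, Q / n
    if P1 == P2 == Q == 0:
        return 0.0
    w1 = 1 - gR * P1 / (2 * gA * gG) - Q / (2 * gR)
    w2 = 1 - gY * P2 / (2 * gT * gC) - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return math.inf
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    if gamma_shape is None:
        return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    ai = 1 / gamma_shape
    return gamma_shape * (
        k1 * (w1**-ai - 1) + k2 * (w2**-ai - 1) + k3 * (w3**-ai - 1)
    )
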