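"""Distance-based phylogenetics: p/TN93 distances, neighbor-joining and
nonparametric bootstrap supports.

Distances use pairwise deletion (a column is compared for a pair only when
both bases are unambiguous nucleotides).  The TN93 distance corrects the two
transition classes separately from transversions using empirical base
frequencies; the gamma variant applies the standard rate-heterogeneity
correction with shape ``a``.  Neighbor-joining is the classical Saitou-Nei
agglomeration with Q-matrix selection and deterministic tie-breaking by
lowest label pair; negative branch-length estimates are clamped to zero and
flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

COMPARABLE = set("ACGT")


# --- distances ------------------------------------------------------------


def _paired_columns(a: str, b: str) -> list[tuple[str, str]]:
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    return [(x, y) for x, y in zip(a, b) if x in COMPARABLE and y in COMPARABLE]


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among pairwise-comparable columns."""
    cols = _paired_columns(a, b)
    if not cols:
        raise ValueError("no comparable columns between the two sequences")
    diff = sum(1 for x, y in cols if x != y)
    return diff / len(cols)


TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def tn93_distance(a: str, b: str, gamma_shape: Optional[float] = None) -> float:
    """Tamura-Nei (1993) distance, optionally gamma-corrected.

    Returns ``inf`` when a logarithm argument is non-positive (substitution
    saturation for this pair).
    """
    cols = _paired_columns(a, b)
    n = len(cols)
    if n == 0:
        raise ValueError("no comparable columns between the two sequences")

    freq = {c: 0 for c in "ACGT"}
    p1 = p2 = q = 0
    for x, y in cols:
        freq[x] += 1
        freq[y] += 1
        if x != y:
            if (x, y) in TRANSITIONS:
                if {x, y} == {"A", "G"}:
                    p1 += 1
                else:
                    p2 += 1
            else:
                q += 1
    tot = 2 * n
    pA, pC, pG, pT = (freq[c] / tot for c in "ACGT")
    pR, pY = pA + pG, pC + pT
    P1, P2, Q = p1 / n, p2 / n, q / n
    if P1 == 0 and P2 == 0 and Q == 0:
        return 0.0

    k1 = 2 * pA * pG / pR if pR > 0 else 0.0
    k2 = 2 * pT * pC / pY if pY > 0 else 0.0
    k3 = 0.0
    if pR > 0 and pY > 0:
        k3 = 2 * (pR * pY - pA * pG * pY / pR - pT * pC * pR / pY)

    terms = []
    if k1 > 0:
        terms.append((k1, 1 - P1 / k1 - Q / (2 * pR)))
    if k2 > 0:
        terms.append((k2, 1 - P2 / k2 - Q / (2 * pY)))
    if k3 > 0:
        terms.append((k3, 1 - Q / (2 * pR * pY)))
    if any(w <= 0 for _, w in terms):
        return math.inf
    if gamma_shape is None:
        return -sum(k * math.log(w) for k, w in terms)
    ainv = 1.0 / gamma_shape
    return gamma_shape * sum(k * (w ** -ainv - 1) for k, w in terms)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite & finite.T], self.values.T[finite & finite.T]
        ):
            raise ValueError("distance matrix must be symmetric")

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        return path


def distance_matrix(
    msa: Mapping[str, str],
    model: str = "tn93",
    gamma_shape: Optional[float] = None,
) -> DistanceMatrix:
    """All-pairs distances from an aligned sequence set (pairwise deletion)."""
    labels = list(msa)
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if model == "p":
                d = p_distance(msa[labels[i]], msa[labels[j]])
            elif model == "tn93":
                d = tn93_distance(msa[labels[i]], msa[labels[j]], gamma_shape)
            else:
                raise ValueError(f"unknown model {model!r}")
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels=labels, values=vals)


# --- trees ----------------------------------------------------------------


@dataclass
class Node:
    label: str | None = None
    length: float = 0.0  # branch length to the parent
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """An unrooted tree stored with an arbitrary trifurcating root."""

    root: Node
    clamped_branches: int = 0  # negative NJ estimates clamped to zero

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def newick(self, include_supports: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            sup = ""
            if include_supports and node.support is not None:
                sup = f"{node.support:g}"
            return f"({inner}){sup}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial splits, each canonicalized as the side not containing
        the alphabetically first leaf."""
        all_leaves = set(self.leaf_labels)
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: Node) -> set[str]:
            if node.is_leaf:
                return {node.label}
            below: set[str] = set()
            for c in node.children:
                below |= walk(c)
            side = below if anchor not in below else all_leaves - below
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(frozenset(side))
            return below

        for c in self.root.children:
            walk(c)
        return splits

    def attach_supports(self, support_of: Mapping[frozenset[str], float]) -> None:
        all_leaves = set(self.leaf_labels)
        anchor = min(all_leaves)

        def walk(node: Node) -> set[str]:
            if node.is_leaf:
                return {node.label}
            below: set[str] = set()
            for c in node.children:
                below |= walk(c)
            side = below if anchor not in below else all_leaves - below
            key = frozenset(side)
            if key in support_of:
                node.support = support_of[key]
            return below

        for c in self.root.children:
            walk(c)


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Classical Saitou-Nei neighbor joining.

    Tie-breaking: among pairs minimizing Q, the pair whose (sorted) canonical
    labels are lexicographically smallest is joined.  Canonical label of an
    internal node is the smallest leaf label beneath it.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(d.values)):
        raise ValueError("distance matrix contains saturated (infinite) entries")

    nodes: list[Node] = [Node(label=lab) for lab in d.labels]
    canon: list[str] = list(d.labels)
    D = d.values.astype(float).copy()
    active = list(range(n))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best: tuple[str, str] | None = None
        bi = bj = -1
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((canon[active[a]], canon[active[b]])))
                    if best is None or key < best:
                        best, bi, bj = key, a, b
        i, j = active[bi], active[bj]
        dij = D[i, j]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = dij - li
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = clamp(li), clamp(lj)
        parent = Node(children=[ni, nj])
        # distances from the new node to the remaining actives
        newrow = np.zeros(D.shape[0] + 1)
        for b in range(m):
            k = active[b]
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newrow) - 1] = newrow[:-1]
        D[: len(newrow) - 1, -1] = newrow[:-1]
        nodes.append(parent)
        canon.append(min(canon[i], canon[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # terminal 3-star: closed-form branch lengths
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    nodes[a].length = clamp(la)
    nodes[b].length = clamp(lb)
    nodes[c].length = clamp(lc)
    order = sorted((a, b, c), key=lambda k: canon[k])
    root = Node(children=[nodes[k] for k in order])
    return PhyloTree(root=root, clamped_branches=clamped)


def bootstrap(
    msa: Mapping[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "tn93",
    gamma_shape: Optional[float] = None,
) -> tuple[PhyloTree, dict[frozenset[str], float]]:
    """Column-resampling bootstrap supports for the NJ tree of ``msa``.

    Returns the full-data tree with supports attached (percent of replicates
    containing each of its splits) and the full split -> support map over all
    replicate splits.  Replicates whose distance matrix is degenerate
    (saturated pair) are skipped and counted out of the denominator.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = list(msa)
    L = len(next(iter(msa.values())))
    if any(len(s) != L for s in msa.values()):
        raise ValueError("bootstrap requires equal-length aligned sequences")

    full = neighbor_joining(distance_matrix(msa, model, gamma_shape))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    used = 0
    arr = {lab: np.frombuffer(s.encode(), dtype=np.uint8) for lab, s in msa.items()}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = {lab: arr[lab][cols].tobytes().decode() for lab in labels}
        try:
            tree = neighbor_joining(distance_matrix(resampled, model, gamma_shape))
        except ValueError:
            continue
        used += 1
        for split in tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    if used == 0:
        raise ValueError("all bootstrap replicates were degenerate")
    supports = {split: 100.0 * c / used for split, c in counts.items()}
    full.attach_supports(supports)
    return full, supports


def write_newick(tree: PhyloTree, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(tree.newick() + "\n")
    return path


def build_pseudo_msa(alignments: Mapping[str, "object"], ref_seq: str) -> dict[str, str]:
    """Stack pairwise reference alignments into reference-coordinate columns.

    Each query contributes its base at every reference position ('-' where
    the query is deleted); insertions relative to the reference are dropped.
    The reference itself is included under the alignments' ref_id.
    """
    out: dict[str, str] = {}
    ref_id = None
    for qid, aln in alignments.items():
        ref_id = aln.ref_id
        row = []
        for cr, cq in zip(aln.aligned_ref, aln.aligned_qry):
            if cr != "-":
                row.append(cq)
        if len(row) != len(ref_seq):
            raise ValueError("alignment does not cover the reference")
        out[qid] = "".join(row)
    if ref_id is not None:
        out[ref_id] = ref_seq
    return out
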