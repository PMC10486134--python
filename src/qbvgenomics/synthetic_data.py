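"""Synthetic flavivirus-like genomes with fully known ground truth.

The generator emulates the architecture of a Quang Binh virus genome: a
~98-nt 5'UTR, a single 10,080-nt ORF (one polyprotein, stop codon included)
partitioned into the 11 contiguous mature-peptide regions used for
per-region statistics, and a ~653-nt 3'UTR.  Isolates are derived from the
reference by planting per-region synonymous/nonsynonymous substitutions
with a transition bias, slippery-heptamer + hairpin features for frameshift
detection, or by evolving sequences along a known tree — in every case the
manifest records the exact truth so each pipeline stage can be checked for
exact recovery.

The defaults reproduce the geometry of the study system (10,831-nt genome,
10,077 nt of mature-peptide regions = 3,359 codons before the stop).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import expm

from .genome_io import (
    Genome,
    MAT_PEPTIDE_KIND,
    Region,
    RegionTable,
    UTR_KIND,
)
from .prf import DEFAULT_PATTERNS, to_dna
from .variants import NONCODING, NONSYNONYMOUS, SNVRecord, SYNONYMOUS
from Bio.Seq import Seq

STOPS = ("TAA", "TAG", "TGA")

#: the 11-region mature-peptide partition (lengths in nt, sum = 10,077)
DEFAULT_REGION_NAMES = (
    "AC+C", "PrM+M", "E", "NS1", "NS2A", "NS2B", "NS3", "NS4A", "2K", "NS4B", "NS5",
)
DEFAULT_REGION_LENGTHS = (408, 426, 1281, 1179, 606, 438, 1764, 465, 69, 774, 2667)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _scrub_patterns(
    seq: list[str],
    rng: np.random.Generator,
    orf_start: int,
    orf_end: int,
    protected: set[int] | None = None,
    max_rounds: int = 100,
) -> None:
    """Remove every slippery-heptamer occurrence by point changes, keeping
    the reading frame free of new stop codons.  ``protected`` positions
    (0-based) are never modified."""
    protected = protected or set()
    targets = [to_dna(p) for p in DEFAULT_PATTERNS]
    for _ in range(max_rounds):
        s = "".join(seq)
        hit = None
        for t in targets:
            idx = s.find(t)
            if idx != -1 and (hit is None or idx < hit):
                hit = idx
        if hit is None:
            return
        # mutate a non-protected base in the heptamer to C or G
        cands = [i for i in range(hit, hit + 7) if i not in protected]
        if not cands:
            raise ValueError("slippery pattern overlaps protected bases; cannot scrub")
        done = False
        for pos in rng.permutation(cands):
            pos = int(pos)
            for nb in "CG":
                if seq[pos] == nb:
                    continue
                old = seq[pos]
                seq[pos] = nb
                if orf_start - 1 <= pos < orf_end:
                    cstart = orf_start - 1 + 3 * ((pos - (orf_start - 1)) // 3)
                    codon = "".join(seq[cstart : cstart + 3])
                    if codon in STOPS or (cstart == orf_start - 1 and codon != "ATG"):
                        seq[pos] = old
                        continue
                done = True
                break
            if done:
                break
        if not done:
            raise ValueError("could not scrub slippery pattern")
    raise ValueError("pattern scrubbing did not converge")


def generate_reference(
    utr5_len: int = 98,
    cds_len: int = 10080,
    utr3_len: int = 653,
    region_lengths: Sequence[int] = DEFAULT_REGION_LENGTHS,
    region_names: Sequence[str] = DEFAULT_REGION_NAMES,
    gc: float = 0.5,
    seed: int = 0,
    genome_id: str = "synthetic_ref",
    forbid_slippery: bool = False,
) -> tuple[Genome, RegionTable]:
    """A random genome with one clean ORF and its region table.

    The mature-peptide regions tile the ORF minus the final stop codon
    (their lengths must sum to ``cds_len`` - 3, matching the convention of
    coordinate tables that exclude the stop); the ORF itself starts with ATG,
    ends with a stop and contains no internal in-frame stop.  With
    ``forbid_slippery`` the genome is additionally free of all five slippery
    heptamer patterns (useful before planting frameshift sites).
    """
    if cds_len % 3 != 0:
        raise ValueError("cds_len must be divisible by 3")
    if sum(region_lengths) != cds_len - 3:
        raise ValueError(
            f"region lengths sum to {sum(region_lengths)}, need cds_len-3 = {cds_len - 3}"
        )
    if len(region_lengths) != len(region_names):
        raise ValueError("region_names and region_lengths must match")
    rng = np.random.default_rng(seed)

    n_codons = cds_len // 3 - 2  # between the ATG and the stop
    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codons = []
    while len(codons) < n_codons:
        draw = bases[rng.choice(4, size=(n_codons - len(codons) + 16, 3), p=p)]
        for row in draw:
            c = "".join(row)
            if c not in STOPS:
                codons.append(c)
            if len(codons) == n_codons:
                break
    cds = "ATG" + "".join(codons) + STOPS[rng.integers(0, 3)]
    seq = _random_seq(rng, utr5_len, gc) + cds + _random_seq(rng, utr3_len, gc)

    orf_start = utr5_len + 1
    orf_end = utr5_len + cds_len
    chars = list(seq)
    # no ATG in the ORF's frame upstream of the start codon, so the planted
    # ORF is exactly what a three-frame scan reports for its interval
    for pos in range(utr5_len - 3, -1, -3):
        if "".join(chars[pos : pos + 3]) == "ATG":
            chars[pos + 2] = "C"
    if forbid_slippery:
        _scrub_patterns(chars, rng, orf_start, orf_end)
    genome = Genome(id=genome_id, sequence="".join(chars))

    regions = []
    if utr5_len > 0:
        regions.append(Region("5UTR", 1, utr5_len, UTR_KIND))
    pos = orf_start
    for name, L in zip(region_names, region_lengths):
        regions.append(Region(name, pos, pos + L - 1, MAT_PEPTIDE_KIND))
        pos += L
    if utr3_len > 0:
        regions.append(Region("3UTR", orf_end + 1, genome.length, UTR_KIND))
    table = RegionTable(
        reference_id=genome_id, regions=regions, orf_start=orf_start, orf_end=orf_end
    )
    return genome, table


def _codon_aa(codon: str) -> str:
    return str(Seq(codon).translate())


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def plant_snvs(
    ref: Genome,
    table: RegionTable,
    spec: Mapping[str, tuple[int, int]],
    ts_tv_bias: float = 2.0,
    seed: int = 0,
    isolate_id: str = "isolate",
    allow_multihit: bool = False,
    max_tries: int = 1000,
) -> tuple[Genome, list[SNVRecord]]:
    """Derive a mutant genome carrying exactly the requested per-region
    (n_synonymous, n_nonsynonymous) substitution counts.

    Substitution types are drawn with a transition:transversion weight of
    ``ts_tv_bias``:1 per alternative base; each planted SNV's effect is
    verified by codon translation before emission, and nonsense changes are
    never planted (every nonsynonymous SNV changes exactly one residue).
    For UTR regions the first count is planted as noncoding SNVs (the second
    must be 0).  Unless ``allow_multihit``, no codon receives two SNVs.
    """
    rng = np.random.default_rng(seed)
    orf_start, orf_end = table.orf_start, table.orf_end
    chars = list(ref.sequence)
    used_positions: set[int] = set()
    used_codons: set[int] = set()
    truth: list[SNVRecord] = []
    region_of = {r.name: r for r in table.regions}

    def draw_alt(base: str) -> str:
        alts = [b for b in "ACGT" if b != base]
        w = np.array([ts_tv_bias if _TRANSITION[base] == b else 1.0 for b in alts])
        return alts[rng.choice(3, p=w / w.sum())]

    def plant_one(region: Region, want: str) -> None:
        for _ in range(max_tries):
            pos = int(rng.integers(region.start, region.end + 1))  # 1-based
            if pos in used_positions:
                continue
            coding = orf_start is not None and orf_start <= pos <= orf_end
            if want == NONCODING:
                if coding:
                    continue
                alt = draw_alt(chars[pos - 1])
                used_positions.add(pos)
                chars[pos - 1] = alt
                truth.append(
                    SNVRecord(
                        ref_pos=pos,
                        ref_base=ref.sequence[pos - 1],
                        alt_base=alt,
                        sample=isolate_id,
                        region=region.name,
                        effect=NONCODING,
                    )
                )
                return
            if not coding:
                continue
            offset = pos - orf_start
            codon_index = offset // 3 + 1
            if not allow_multihit and codon_index in used_codons:
                continue
            codon_pos = offset % 3 + 1
            cstart = orf_start + 3 * (codon_index - 1)
            ref_codon = ref.sequence[cstart - 1 : cstart + 2]
            alt = draw_alt(ref.sequence[pos - 1])
            alt_codon = ref_codon[: codon_pos - 1] + alt + ref_codon[codon_pos:]
            ref_aa, alt_aa = _codon_aa(ref_codon), _codon_aa(alt_codon)
            if alt_aa == "*":
                continue  # never plant nonsense changes
            effect = SYNONYMOUS if ref_aa == alt_aa else NONSYNONYMOUS
            if effect != want:
                continue
            used_positions.add(pos)
            used_codons.add(codon_index)
            chars[pos - 1] = alt
            truth.append(
                SNVRecord(
                    ref_pos=pos,
                    ref_base=ref.sequence[pos - 1],
                    alt_base=alt,
                    sample=isolate_id,
                    region=region.name,
                    codon_index=codon_index,
                    codon_pos=codon_pos,
                    ref_codon=ref_codon,
                    alt_codon=alt_codon,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    effect=effect,
                )
            )
            return
        raise ValueError(
            f"could not plant a {want} SNV in region {region.name!r} "
            f"after {max_tries} tries"
        )

    for name, (n_first, n_second) in spec.items():
        if name not in region_of:
            raise ValueError(f"unknown region {name!r} in SNV spec")
        region = region_of[name]
        if region.kind == UTR_KIND:
            if n_second:
                raise ValueError(f"UTR region {name!r} cannot take nonsynonymous SNVs")
            for _ in range(n_first):
                plant_one(region, NONCODING)
        else:
            for _ in range(n_first):
                plant_one(region, SYNONYMOUS)
            for _ in range(n_second):
                plant_one(region, NONSYNONYMOUS)

    truth.sort(key=lambda s: s.ref_pos)
    return Genome(id=isolate_id, sequence="".join(chars)), truth


@dataclass
class PlantedPrfSite:
    pattern: str
    start: int  # 1-based heptamer start
    stem: int
    loop: int
    offset: int  # nt between heptamer end and the 5' stem arm


def plant_prf_site(
    g: Genome,
    position: int,
    pattern: str = "GGAUUUC",
    hairpin: Mapping[str, int] | None = None,
    seed: int = 0,
) -> tuple[Genome, PlantedPrfSite]:
    """Write a slippery heptamer at ``position`` and a clean hairpin in its
    downstream window.

    The hairpin sits ``offset`` nt after the heptamer: a random GC-rich 5'
    arm of ``stem`` nt, an unpairable loop (A/C alphabet), and the reverse
    complement 3' arm.  Flanking bases are set unpairable so the planted
    helix has exactly the stated dimensions, and any heptamer-pattern match
    accidentally created by planting is scrubbed from non-feature bases.
    Raises if the feature window collides with an existing pattern match or
    the genome end.
    """
    hp = {"stem": 8, "loop": 5, "offset": 10}
    if hairpin:
        hp.update(hairpin)
    stem, loop, offset = hp["stem"], hp["loop"], hp["offset"]
    rng = np.random.default_rng(seed)

    feat_end = position + 6 + offset + 2 * stem + loop + 2
    if position < 3 or feat_end > g.length or position + 6 + 150 > g.length:
        raise ValueError("site and its 150-nt downstream window must fit in the genome")

    from .prf import scan_slippery  # local import to avoid cycle at module load

    pre = {(p, s) for p, s in scan_slippery(g)}
    for _, s in pre:
        if abs(s - position) < 7 or position + 7 <= s <= feat_end:
            raise ValueError(f"collision with an existing pattern occurrence at {s}")

    chars = list(g.sequence)
    protected: set[int] = set()

    def put(idx0: int, s: str) -> None:
        for k, c in enumerate(s):
            chars[idx0 + k] = c
            protected.add(idx0 + k)

    put(position - 1, to_dna(pattern))
    arm_start = position + 6 + offset  # 0-based index of 5' arm
    arm = "".join(np.array(list("GC"))[rng.integers(0, 2, size=stem)])
    # one A->U-free loop and unpairable flanks (A cannot pair with A or C)
    loop_seq = "".join(np.array(list("AC"))[rng.integers(0, 2, size=loop)])
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    arm_rc = "".join(comp[c] for c in reversed(arm))
    put(arm_start - 2, "AA")
    put(arm_start, arm)
    put(arm_start + stem, loop_seq)
    put(arm_start + stem + loop, arm_rc)
    put(arm_start + 2 * stem + loop, "AA")

    mutant = Genome(id=g.id, sequence="".join(chars))
    post = {(p, s) for p, s in scan_slippery(mutant)}
    expected = pre | {(pattern, position)}
    extra = post - expected
    if extra:
        # break accidental matches at non-feature bases
        _scrub_extra(chars, extra, protected, rng)
        mutant = Genome(id=g.id, sequence="".join(chars))
        post = {(p, s) for p, s in scan_slippery(mutant)}
        if post - expected:
            raise ValueError("planting created unremovable extra pattern matches")
    return mutant, PlantedPrfSite(
        pattern=pattern, start=position, stem=stem, loop=loop, offset=offset
    )


def _scrub_extra(chars, extra, protected, rng) -> None:
    for _, s in extra:
        cands = [i for i in range(s - 1, s + 6) if i not in protected]
        if not cands:
            raise ValueError("accidental pattern lies entirely inside planted features")
        pos = int(rng.choice(cands))
        chars[pos] = "C" if chars[pos] != "C" else "G"


# --- evolution along a tree ----------------------------------------------


def _rate_matrix(model: str, freqs: Sequence[float], kappa: float) -> np.ndarray:
    """Normalized GTR-family rate matrix (JC or TN93-style with a single
    transition/transversion ratio ``kappa`` for both transition classes)."""
    pi = np.asarray(freqs, dtype=float)
    pi = pi / pi.sum()
    Q = np.zeros((4, 4))
    order = "ACGT"
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j]
            if (order[i], order[j]) in (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")):
                rate *= kappa
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    return Q / scale


def evolve_on_tree(
    ref: Genome,
    tree_newick: str,
    model: str = "JC",
    seed: int = 0,
    kappa: float = 2.0,
    freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> dict[str, Genome]:
    """Simulate sequences site-independently along a Newick tree whose
    branch lengths are in substitutions/site; the reference is the root
    state.  Returns one genome per named leaf."""
    import dendropy

    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    if model.upper() == "JC":
        Q = _rate_matrix("JC", (0.25,) * 4, 1.0)
    elif model.upper() in ("TN93", "K2P", "HKY"):
        Q = _rate_matrix(model, freqs, kappa)
    else:
        raise ValueError(f"unknown model {model!r}")

    rng = np.random.default_rng(seed)
    idx = {c: i for i, c in enumerate("ACGT")}
    root_state = np.array([idx[c] for c in ref.sequence], dtype=np.int8)
    out: dict[str, Genome] = {}

    def descend(node, state: np.ndarray) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            if t < 0:
                raise ValueError("negative branch length")
            if t == 0:
                child_state = state.copy()
            else:
                P = expm(Q * t)
                child_state = state.copy()
                for b in range(4):
                    mask = state == b
                    n = int(mask.sum())
                    if n:
                        child_state[mask] = rng.choice(4, size=n, p=P[b])
            if child.is_leaf():
                label = child.taxon.label if child.taxon else "leaf"
                out[label.replace(" ", "_")] = Genome(
                    id=label.replace(" ", "_"),
                    sequence="".join("ACGT"[i] for i in child_state),
                )
            else:
                descend(child, child_state)

    descend(tree.seed_node, root_state)
    return out


# --- whole-study simulation ----------------------------------------------


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for exact-recovery checks."""

    reference: Genome
    region_table: RegionTable
    isolates: list[Genome]
    planted_snvs: dict[str, list[SNVRecord]]
    planted_sites: list[PlantedPrfSite] = field(default_factory=list)
    seed: int = 0

    def snv_counts(self, isolate_id: str) -> dict[str, tuple[int, int]]:
        """Per-region (total, nonsynonymous) planted counts."""
        out: dict[str, list[int]] = {}
        for s in self.planted_snvs[isolate_id]:
            tot_ns = out.setdefault(s.region, [0, 0])
            tot_ns[0] += 1
            if s.effect == NONSYNONYMOUS:
                tot_ns[1] += 1
        return {k: (v[0], v[1]) for k, v in out.items()}

    def write_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "reference": self.reference.id,
            "isolates": [g.id for g in self.isolates],
            "regions": self.region_table.to_frame().to_dict(orient="records"),
            "orf": [self.region_table.orf_start, self.region_table.orf_end],
            "planted_snvs": {
                k: [asdict(s) for s in v] for k, v in self.planted_snvs.items()
            },
            "planted_sites": [asdict(s) for s in self.planted_sites],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def simulate_isolates(
    spec_by_isolate: Mapping[str, Mapping[str, tuple[int, int]]],
    seed: int = 0,
    ts_tv_bias: float = 2.0,
    reference_kwargs: Mapping | None = None,
) -> SyntheticTruth:
    """Generate a reference and one planted-SNV isolate per spec entry."""
    rng = np.random.default_rng(seed)
    ref_seed = int(rng.integers(0, 2**31 - 1))
    ref, table = generate_reference(seed=ref_seed, **(reference_kwargs or {}))
    isolates: list[Genome] = []
    planted: dict[str, list[SNVRecord]] = {}
    for name, spec in spec_by_isolate.items():
        iso_seed = int(rng.integers(0, 2**31 - 1))
        iso, truth = plant_snvs(
            ref, table, spec, ts_tv_bias=ts_tv_bias, seed=iso_seed, isolate_id=name
        )
        isolates.append(iso)
        planted[name] = truth
    return SyntheticTruth(
        reference=ref,
        region_table=table,
        isolates=isolates,
        planted_snvs=planted,
        seed=seed,
    )
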