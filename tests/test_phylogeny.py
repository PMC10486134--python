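import math

import dendropy
import numpy as np
import pytest

from qbvgenomics.phylogeny import (
    DistanceMatrix,
    bootstrap,
    build_pseudo_msa,
    distance_matrix,
    neighbor_joining,
    p_distance,
    tn93_distance,
    write_newick,
)

from .oracles import best_topology_exhaustive, tn93_reference


def _random_seqs(rng, n, L, divergence):
    root = rng.choice(list("ACGT"), L)
    out = {}
    for i in range(n):
        s = root.copy()
        mask = rng.random(L) < divergence
        for j in np.where(mask)[0]:
            s[j] = rng.choice([b for b in "ACGT" if b != s[j]])
        out[f"t{i}"] = "".join(s)
    return out


class TestPDistance:
    def test_identical_and_simple_fraction(self):
        assert p_distance("ACGT", "ACGT") == 0.0
        a = "A" * 90 + "C" * 10
        b = "A" * 90 + "G" * 10
        assert p_distance(a, b) == 0.10

    def test_pairwise_deletion_excludes_gap_columns(self):
        assert p_distance("AC-T", "ACGT") == 0.0
        assert p_distance("ACNT", "ACGT") == 0.0

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(ValueError):
            p_distance("----", "ACGT")


class TestTN93:
    def test_zero_for_identical(self):
        assert tn93_distance("ACGTACGT" * 10, "ACGTACGT" * 10) == 0.0

    def test_at_least_p_distance_on_random_pairs(self, rng):
        for _ in range(50):
            msa = _random_seqs(rng, 2, 400, 0.08)
            a, b = msa.values()
            assert tn93_distance(a, b) >= p_distance(a, b) - 1e-12

    def test_matches_independent_transcription_of_the_formula(self, rng):
        for gamma in (None, 1.0, 0.5):
            for _ in range(20):
                msa = _random_seqs(rng, 2, 300, 0.1)
                a, b = msa.values()
                assert tn93_distance(a, b, gamma) == pytest.approx(
                    tn93_reference(a, b, gamma), rel=1e-12
                )

    def test_gamma_correction_increases_distance(self, rng):
        msa = _random_seqs(rng, 2, 500, 0.1)
        a, b = msa.values()
        assert tn93_distance(a, b, gamma_shape=1.0) > tn93_distance(a, b)

    def test_saturation_flags_infinite_distance(self):
        # maximally divergent: every site a transversion
        a = "A" * 50 + "C" * 50
        b = "C" * 50 + "A" * 50
        assert math.isinf(tn93_distance(a, b))


class TestNeighborJoining:
    def test_four_taxa_additive_recovers_known_topology(self):
        # tree ((A,B),(C,D)) with internal edge 2: additive distances
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 7, 8],
                [3, 0, 8, 9],
                [7, 8, 0, 5],
                [8, 9, 5, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, D))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        # total path length A-B reproduces the additive distance
        t = dendropy.Tree.get(data=tree.newick(), schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        tax = {x.label: x for x in t.taxon_namespace}
        assert pdm.distance(tax["A"], tax["B"]) == pytest.approx(3.0)
        assert pdm.distance(tax["A"], tax["D"]) == pytest.approx(8.0)

    def test_three_taxa_closed_form_branch_lengths(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], D))
        lengths = {n.label: n.length for n in tree.root.children}
        assert lengths == {"a": 1.0, "b": 3.0, "c": 5.0}

    def test_matches_exhaustive_topology_search_on_additive_instances(self, rng):
        for n in (4, 5, 6):
            for rep in range(5):
                labels = [f"t{i}" for i in range(n)]
                # build a random additive matrix from a random tree
                nwk = _random_tree_newick(labels, rng)
                D = _tree_distances(nwk, labels)
                got = neighbor_joining(DistanceMatrix(labels, D)).bipartitions()
                want = best_topology_exhaustive(labels, D)
                assert got == want

    def test_agrees_with_dendropy_nj_on_random_matrices(self, rng):
        labels = [f"t{i}" for i in range(6)]
        nwk = _random_tree_newick(labels, rng)
        D = _tree_distances(nwk, labels)
        got = neighbor_joining(DistanceMatrix(labels, D)).bipartitions()
        dtree = _dendropy_pdm(labels, D).nj_tree()
        assert got == _dendropy_splits(dtree, labels)

    def test_fewer_than_three_taxa_is_an_error(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_asymmetric_matrix_rejected(self):
        vals = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], vals)

    def test_negative_branch_estimates_clamped(self):
        D = np.array(
            [[0, 0.1, 0.4, 0.4],
             [0.1, 0, 0.4, 0.4],
             [0.4, 0.4, 0, 0.01],
             [0.4, 0.4, 0.01, 0]]
        )
        tree = neighbor_joining(DistanceMatrix(list("abcd"), D))
        assert all(n.length >= 0 for n in _all_nodes(tree.root))


class TestBootstrap:
    def test_fixed_seed_reproducible(self, rng):
        msa = _random_seqs(rng, 5, 200, 0.1)
        t1, s1 = bootstrap(msa, n_reps=30, seed=7)
        t2, s2 = bootstrap(msa, n_reps=30, seed=7)
        assert s1 == s2 and t1.newick() == t2.newick()

    def test_single_replicate_supports_are_zero_or_hundred(self, rng):
        msa = _random_seqs(rng, 5, 300, 0.1)
        _, supports = bootstrap(msa, n_reps=1, seed=3)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_strong_clade_signal_gets_high_support(self, rng):
        # two well-separated clades: many columns support the central split
        L = 400
        base = rng.choice(list("ACGT"), L)
        other = base.copy()
        idx = rng.choice(L, size=L // 4, replace=False)
        for j in idx:
            other[j] = {"A": "G", "G": "A", "C": "T", "T": "C"}[other[j]]
        def jiggle(arr, k):
            arr = arr.copy()
            for j in rng.choice(L, size=k, replace=False):
                arr[j] = rng.choice([b for b in "ACGT" if b != arr[j]])
            return "".join(arr)
        msa = {
            "a1": jiggle(base, 4), "a2": jiggle(base, 4),
            "b1": jiggle(other, 4), "b2": jiggle(other, 4),
        }
        tree, supports = bootstrap(msa, n_reps=100, seed=11)
        central = frozenset({"b1", "b2"})
        assert supports[central] >= 95.0

    def test_taxon_order_does_not_change_supports(self, rng):
        msa = _random_seqs(rng, 5, 300, 0.15)
        _, s1 = bootstrap(msa, n_reps=25, seed=5)
        reordered = dict(reversed(list(msa.items())))
        _, s2 = bootstrap(reordered, n_reps=25, seed=5)
        assert s1 == s2


class TestNewick:
    def test_three_taxon_shape_and_round_trip(self, tmp_path):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], D))
        p = write_newick(tree, tmp_path / "t.nwk")
        text = p.read_text().strip()
        assert text.startswith("(") and text.endswith(");")
        parsed = dendropy.Tree.get(path=str(p), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == {"A", "B", "C"}
        pdm = parsed.phylogenetic_distance_matrix()
        tax = {x.label: x for x in parsed.taxon_namespace}
        assert pdm.distance(tax["A"], tax["B"]) == pytest.approx(4.0)

    def test_supports_serialized_as_internal_labels(self, rng):
        msa = _random_seqs(rng, 4, 200, 0.1)
        tree, supports = bootstrap(msa, n_reps=10, seed=1)
        if supports:
            nwk = tree.newick()
            parsed = dendropy.Tree.get(data=nwk, schema="newick")
            internal_labels = [
                n.label for n in parsed.internal_nodes() if n.label is not None
            ]
            assert internal_labels  # at least one support made it through


class TestPseudoMsa:
    def test_stacks_reference_coordinates(self, small_reference):
        from qbvgenomics.pairwise_align import global_align
        from qbvgenomics.synthetic_data import plant_snvs

        g, table = small_reference
        iso, truth = plant_snvs(g, table, {"R2": (10, 5)}, seed=4, isolate_id="iso")
        msa = build_pseudo_msa({"iso": global_align(g, iso)}, g.sequence)
        assert set(msa) == {"iso", g.id}
        assert len(msa["iso"]) == len(msa[g.id]) == g.length
        assert p_distance(msa["iso"], msa[g.id]) == pytest.approx(15 / g.length)


# --- helpers --------------------------------------------------------------


def _all_nodes(node):
    yield node
    for c in node.children:
        yield from _all_nodes(c)


def _random_tree_newick(labels, rng):
    """Random binary topology with positive branch lengths."""
    nodes = [f"{l}:{rng.uniform(0.05, 0.5):.4f}" for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.05, 0.5):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({','.join(nodes)});"


def _tree_distances(nwk, labels):
    t = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    tax = {x.label: x for x in t.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.distance(tax[labels[i]], tax[labels[j]])
    return D


def _dendropy_pdm(labels, D):
    csv = "," + ",".join(labels) + "\n"
    for i, l in enumerate(labels):
        csv += l + "," + ",".join(str(x) for x in D[i]) + "\n"
    import io

    return dendropy.PhylogeneticDistanceMatrix.from_csv(
        io.StringIO(csv), delimiter=","
    )


def _dendropy_splits(dtree, labels):
    anchor = min(labels)
    all_leaves = set(labels)
    splits = set()
    for node in dtree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = {t.taxon.label for t in node.leaf_iter()}
        side = below if anchor not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(frozenset(side))
    return splits
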