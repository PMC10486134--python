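import math

import numpy as np
import pytest

from qbvgenomics.annotation import find_orfs
from qbvgenomics.genome_io import UNAMBIGUOUS
from qbvgenomics.pairwise_align import AlignParams, global_align, translate
from qbvgenomics.phylogeny import DistanceMatrix, distance_matrix, neighbor_joining, p_distance
from qbvgenomics.prf import scan_slippery
from qbvgenomics.synthetic_data import (
    evolve_on_tree,
    generate_reference,
    plant_prf_site,
    plant_snvs,
    simulate_isolates,
)
from qbvgenomics.variants import NONSYNONYMOUS, SYNONYMOUS, call_snvs, classify

from .conftest import SMALL_KW


class TestGenerateReference:
    def test_default_geometry_matches_study_system(self):
        g, table = generate_reference(seed=0)
        assert g.length == 10_831
        assert (table.orf_start, table.orf_end) == (99, 10_178)
        assert sum(r.length for r in table.mat_peptides) == 10_077
        assert len(table.mat_peptides) == 11

    def test_orf_is_clean_and_translatable(self):
        g, table = generate_reference(seed=1)
        cds = g.slice1(table.orf_start, table.orf_end)
        aa = translate(cds)
        assert len(aa) == 3359 and "*" not in aa and aa.startswith("M")

    def test_same_seed_reproduces_identical_output(self):
        g1, _ = generate_reference(seed=42)
        g2, _ = generate_reference(seed=42)
        assert g1.sequence == g2.sequence

    def test_different_seed_differs(self):
        g1, _ = generate_reference(seed=1)
        g2, _ = generate_reference(seed=2)
        assert g1.sequence != g2.sequence

    def test_forbid_slippery_removes_all_patterns_and_keeps_orf(self):
        for seed in range(5):
            g, table = generate_reference(seed=seed, forbid_slippery=True)
            assert scan_slippery(g) == []
            orfs = find_orfs(g)
            assert (orfs[0].start, orfs[0].end) == (table.orf_start, table.orf_end)

    def test_inconsistent_region_lengths_rejected(self):
        with pytest.raises(ValueError, match="cds_len-3"):
            generate_reference(seed=0, region_lengths=(100, 100))

    def test_gc_content_honored(self):
        g, _ = generate_reference(seed=3, gc=0.7)
        gc = sum(c in "GC" for c in g.sequence) / g.length
        assert 0.65 < gc < 0.75


class TestPlantSnvs:
    def test_empty_spec_returns_identical_genome(self, small_reference):
        g, table = small_reference
        iso, truth = plant_snvs(g, table, {}, seed=1)
        assert iso.sequence == g.sequence and truth == []

    def test_exact_counts_and_effects(self, small_reference):
        g, table = small_reference
        iso, truth = plant_snvs(g, table, {"R1": (5, 3), "R2": (7, 2)}, seed=2)
        diffs = [i for i, (a, b) in enumerate(zip(g.sequence, iso.sequence)) if a != b]
        assert len(diffs) == len(truth) == 17
        assert sum(t.effect == NONSYNONYMOUS for t in truth) == 5
        assert sum(t.effect == SYNONYMOUS for t in truth) == 12

    def test_truth_verified_by_independent_classification(self, small_reference):
        g, table = small_reference
        iso, truth = plant_snvs(g, table, {"R2": (10, 6)}, seed=3, isolate_id="iso")
        called = classify(call_snvs(global_align(g, iso)), g, table)
        assert called == truth

    def test_no_codon_double_hits_by_default(self, small_reference):
        g, table = small_reference
        _, truth = plant_snvs(g, table, {"R1": (40, 20)}, seed=4)
        codons = [t.codon_index for t in truth]
        assert len(codons) == len(set(codons))

    def test_nonsense_changes_never_planted(self, small_reference):
        g, table = small_reference
        _, truth = plant_snvs(g, table, {"R1": (0, 60)}, seed=5)
        assert all(t.alt_aa != "*" for t in truth)

    def test_utr_regions_take_noncoding_snvs(self, small_reference):
        g, table = small_reference
        iso, truth = plant_snvs(g, table, {"5UTR": (4, 0)}, seed=6)
        assert len(truth) == 4 and all(t.effect == "noncoding" for t in truth)
        assert all(t.ref_pos <= 40 for t in truth)

    def test_infeasible_request_names_the_region(self, small_reference):
        g, table = small_reference
        with pytest.raises(ValueError, match="R1"):
            plant_snvs(g, table, {"R1": (500, 0)}, seed=7, max_tries=50)

    def test_transition_bias_shapes_spectrum(self, small_reference):
        g, table = small_reference
        _, truth = plant_snvs(g, table, {"R2": (150, 0)}, seed=8, ts_tv_bias=50.0)
        ts = sum(
            1 for t in truth
            if {t.ref_base, t.alt_base} in ({"A", "G"}, {"C", "T"})
        )
        assert ts / len(truth) > 0.8


class TestPlantPrfSite:
    def test_determinism(self):
        base, _ = generate_reference(seed=320, forbid_slippery=True)
        g1, s1 = plant_prf_site(base, position=2000, seed=9)
        g2, s2 = plant_prf_site(base, position=2000, seed=9)
        assert g1.sequence == g2.sequence and s1 == s2

    def test_single_pattern_occurrence_after_planting(self):
        base, _ = generate_reference(seed=321, forbid_slippery=True)
        g, site = plant_prf_site(base, position=2000, seed=10)
        assert scan_slippery(g) == [("GGAUUUC", 2000)]

    def test_collision_with_existing_occurrence_rejected(self):
        base, _ = generate_reference(seed=322, forbid_slippery=True)
        g, _ = plant_prf_site(base, position=2000, seed=11)
        with pytest.raises(ValueError, match="collision"):
            plant_prf_site(g, position=2003, seed=12)

    def test_site_too_close_to_genome_end_rejected(self):
        base, _ = generate_reference(seed=323, forbid_slippery=True)
        with pytest.raises(ValueError):
            plant_prf_site(base, position=base.length - 50, seed=13)


class TestEvolveOnTree:
    def test_zero_length_tree_copies_the_root(self, small_reference):
        g, _ = small_reference
        leaves = evolve_on_tree(g, "(A:0.0,B:0.0);", seed=1)
        assert leaves["A"].sequence == leaves["B"].sequence == g.sequence

    def test_jc_expected_divergence_matches_closed_form(self):
        g, _ = generate_reference(seed=30)  # 10,831 sites
        leaves = evolve_on_tree(g, "(A:0.05,B:0.05);", model="JC", seed=2)
        p = p_distance(leaves["A"].sequence, leaves["B"].sequence)
        expected = 0.75 * (1 - math.exp(-4 * 0.1 / 3))  # 0.0945 at d=0.1
        sd = math.sqrt(expected * (1 - expected) / g.length)
        assert abs(p - expected) < 3 * sd

    def test_negative_branch_length_rejected(self, small_reference):
        g, _ = small_reference
        with pytest.raises(ValueError, match="negative"):
            evolve_on_tree(g, "(A:-0.1,B:0.1);", seed=3)

    def test_nj_on_tn93_distances_recovers_8_taxon_topology(self, small_reference):
        g, _ = small_reference
        nwk = ("(((A:0.02,B:0.02):0.02,(C:0.02,D:0.02):0.02):0.02,"
               "((E:0.02,F:0.02):0.02,(G:0.02,H:0.02):0.02):0.02);")
        leaves = evolve_on_tree(g, nwk, model="JC", seed=4)
        msa = {k: v.sequence for k, v in leaves.items()}
        tree = neighbor_joining(distance_matrix(msa, "tn93"))
        splits = tree.bipartitions()
        for clade in ({"A", "B"}, {"C", "D"}, {"E", "F"}, {"G", "H"}):
            assert frozenset(clade) in splits or frozenset(
                set("ABCDEFGH") - clade
            ) in splits

    def test_tn93_monotone_in_divergence_time(self, small_reference):
        g, _ = small_reference
        ds = []
        for t in np.linspace(0.01, 0.4, 10):
            leaves = evolve_on_tree(g, f"(A:{t/2:.4f},B:{t/2:.4f});", seed=5)
            ds.append(
                distance_matrix(
                    {k: v.sequence for k, v in leaves.items()}, "tn93"
                ).values[0, 1]
            )
        from scipy.stats import spearmanr

        rho, _ = spearmanr(np.linspace(0.01, 0.4, 10), ds)
        assert rho == pytest.approx(1.0)
        assert ds == sorted(ds)


class TestSimulateIsolates:
    def test_manifest_round_trips_and_seed_is_reproducible(self, tmp_path):
        spec = {"isoA": {"R1": (3, 1), "R2": (5, 2)}, "isoB": {"R3": (2, 2)}}
        t1 = simulate_isolates(spec, seed=99, reference_kwargs=SMALL_KW)
        t2 = simulate_isolates(spec, seed=99, reference_kwargs=SMALL_KW)
        assert t1.reference.sequence == t2.reference.sequence
        assert [g.sequence for g in t1.isolates] == [g.sequence for g in t2.isolates]
        p = t1.write_manifest(tmp_path / "truth.json")
        import json

        m = json.loads(p.read_text())
        assert m["isolates"] == ["isoA", "isoB"]
        assert len(m["planted_snvs"]["isoA"]) == 11

    def test_planted_counts_summary(self):
        spec = {"iso": {"R1": (3, 1), "R2": (0, 2)}}
        t = simulate_isolates(spec, seed=5, reference_kwargs=SMALL_KW)
        assert t.snv_counts("iso") == {"R1": (4, 1), "R2": (2, 2)}
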