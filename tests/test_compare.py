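"""Pairwise comparison: homology matching, clusters, rearrangement calls.

Fixture-based checks reproduce the published species comparisons; the
randomized checks hold the implementation to exhaustive brute-force oracles
(all one-to-one matchings; all common oriented arcs).
"""

import numpy as np
import pytest

from mitokaryo.compare import (
    NoHomologyError,
    compare,
    derived_clusters,
    detect_split_merge,
    match_chromosomes,
    shared_clusters,
)
from mitokaryo.io import parse_karyotype
from mitokaryo.phylo import parse_newick
from mitokaryo.simulate import SimConfig, evolve_on_tree, fragmented_root
from conftest import (
    brute_force_shared_runs,
    cluster_keys,
    exhaustive_matching_weight,
    random_karyotype,
)


class TestMatching:
    def test_identity_matching_against_self(self, fx):
        k = fx.karyotypes["Act_sp1"]
        h = match_chromosomes(k, k)
        assert h.pairs == tuple((c.label, c.label) for c in k.chromosomes)
        assert h.unmatched_a == () and h.unmatched_b == ()

    def test_act_m1_matched_to_m1(self, fx):
        h = match_chromosomes(fx.karyotypes["Act_sp1"], fx.karyotypes["Act_sp2"])
        assert ("M1", "M1") in h.pairs
        assert h.weights[("M1", "M1")] == 3

    def test_disjoint_gene_sets_raise(self):
        a = parse_karyotype("species: a\nM1: cox1 cox2\n")
        b = parse_karyotype("species: b\nM1: nad1 nad2\n")
        with pytest.raises(NoHomologyError):
            match_chromosomes(a, b)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        a = random_karyotype(rng, n_genes=10, n_chromosomes=int(rng.integers(2, 4)), species_id="a")
        b = random_karyotype(rng, n_genes=9, n_chromosomes=int(rng.integers(2, 4)), species_id="b")
        try:
            h = match_chromosomes(a, b)
        except NoHomologyError:
            assert not (a.gene_set() & b.gene_set())
            return
        got = sum(h.weights.values())
        assert got == exhaustive_matching_weight(a, b)
        assert all(w >= 1 for w in h.weights.values())


class TestSplitMerge:
    def test_identical_karyotypes_zero_groups(self, fx):
        k = fx.karyotypes["Aus_sp2"]
        h = match_chromosomes(k, k)
        groups, orphans = detect_split_merge(k, k, h)
        assert groups == ()
        assert orphans == {"a": (), "b": ()}

    def test_act_pair_has_exactly_one_group(self, fx):
        a, b = fx.karyotypes["Act_sp1"], fx.karyotypes["Act_sp2"]
        h = match_chromosomes(a, b)
        groups, _ = detect_split_merge(a, b, h)
        assert len(groups) == 1
        (g,) = groups
        assert g.one_side == "a" and g.one_label == "M2"
        assert g.many_labels == ("M2", "M3")

    @pytest.mark.parametrize("seed", range(10))
    def test_single_fission_recovered_as_one_group(self, seed):
        tree = parse_newick("(child:1.0,other:1.0);")
        cfg = SimConfig(fission=1.0, seed=seed, root_karyotype=fragmented_root())
        sim = evolve_on_tree(tree, cfg, events_per_branch=1)
        parent = fragmented_root()
        child = sim.tips["child"]
        ev = next(e for e in sim.events if e.branch == "child" and not e.skipped)
        h = match_chromosomes(parent, child)
        groups, _ = detect_split_merge(parent, child, h)
        assert len(groups) == 1
        (g,) = groups
        assert g.one_side == "a"
        # the two fission products jointly carry the parent chromosome
        merged = frozenset().union(*(child[l].gene_set() for l in g.many_labels))
        assert merged == parent[ev.chrom].gene_set()


class TestSharedClusters:
    def test_austromenopon_six_clusters(self, fx):
        found = shared_clusters(fx.karyotypes["Aus_sp1"], fx.karyotypes["Aus_sp2"])
        names = {repr(c) for c in found}
        assert names == {
            "cox2-cox1-atp6-atp8",
            "nad2-nad5-I",
            "nad3-Y",
            "rrnL-rrnS-L1",
            "nad4L-nad4-E",
            "P-K-S1",
        }

    def test_myrsidea_shared_whole_minichromosome(self, fx):
        found = shared_clusters(fx.karyotypes["Myr_sp1"], fx.karyotypes["Myr_sp2"])
        whole = [c for c in found if c.spans_whole_chromosomes]
        assert len(whole) == 1
        assert set(whole[0].gene_names()) == {
            "Y", "nad5", "L1", "nad3", "S1", "cox2", "cox1", "cox3",
        }

    def test_self_comparison_every_chromosome_whole(self, fx):
        k = fx.karyotypes["Act_sp1"]
        found = shared_clusters(k, k)
        assert sum(c.spans_whole_chromosomes for c in found) == len(k.chromosomes)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = random_karyotype(rng, n_genes=10, n_chromosomes=int(rng.integers(1, 4)), species_id="a")
        b = random_karyotype(rng, n_genes=10, n_chromosomes=int(rng.integers(1, 4)), species_id="b")
        got = cluster_keys(shared_clusters(a, b))
        assert got == brute_force_shared_runs(a, b)

    @pytest.mark.parametrize("seed", range(15))
    def test_symmetric_under_argument_swap(self, seed):
        rng = np.random.default_rng(200 + seed)
        a = random_karyotype(rng, n_genes=12, n_chromosomes=2, species_id="a")
        b = random_karyotype(rng, n_genes=12, n_chromosomes=3, species_id="b")
        ab = cluster_keys(shared_clusters(a, b))
        ba = cluster_keys(shared_clusters(b, a))
        assert ab == ba


class TestDerivedClusters:
    def test_cluster_present_in_reference_excluded(self, fx):
        a = parse_karyotype("species: a\nM1: cox1 L2 cox2\nM2: nad4L nad4 E\n")
        b = parse_karyotype("species: b\nM1: cox1 L2 cox2 nad1\nM2: nad4L nad4 E nad2\n")
        found = shared_clusters(a, b)
        derived = derived_clusters(found, fx.reference)
        names = {repr(c) for c in derived}
        # cox1-L2-cox2 is the ancestral arrangement; nad4L-nad4-E is not
        assert "cox1-L2-cox2" not in names
        assert "nad4L-nad4-E" in names

    def test_actornithophilus_clusters_all_derived(self, fx):
        found = shared_clusters(fx.karyotypes["Act_sp1"], fx.karyotypes["Act_sp2"])
        assert len(derived_clusters(found, fx.reference)) == len(found) == 6

    def test_simulated_translocation_creates_derived_cluster(self):
        tree = parse_newick("(child:1.0,other:1.0);")
        root = fragmented_root()
        cfg = SimConfig(translocation=1.0, max_block=3, seed=5, root_karyotype=root)
        sim = evolve_on_tree(tree, cfg, events_per_branch=1)
        child = sim.tips["child"]
        found = shared_clusters(root, child)
        derived = derived_clusters(found, root)
        # every shared run between parent and child exists in the parent
        assert derived == []


class TestCompareReports:
    def test_actornithophilus_worked_example(self, fx):
        rep = compare(fx.karyotypes["Act_sp1"], fx.karyotypes["Act_sp2"])
        assert rep.chromosome_count_delta == -1
        assert len(rep.split_merge_groups) == 1
        assert set(rep.translocated) == {"Q", "W", "L1", "nad5", "D", "L2"}
        assert set(rep.inverted) == {"A", "Q", "W"}
        assert rep.shared_whole_chromosomes == 1

    def test_laemobothrion_identical_pair(self, fx):
        rep = compare(fx.karyotypes["L_sp1"], fx.karyotypes["L_sp3"])
        assert rep.chromosome_count_delta == 0
        assert rep.translocated == () and rep.inverted == ()
        assert rep.repositioned == ()
        assert rep.shared_whole_chromosomes == 1

    def test_laemobothrion_seven_relocated_genes(self, fx):
        rep = compare(fx.karyotypes["L_sp2"], fx.karyotypes["L_sp1"])
        assert rep.chromosome_count_delta == 0
        assert rep.translocated == () and rep.inverted == ()
        assert set(rep.repositioned) == {"nad3", "G", "W", "V", "F", "M", "Q"}

    def test_self_comparison_is_empty(self, fx):
        for species in ("Aus_sp2", "Myr_sp1", "L_tinnunculi"):
            k = fx.karyotypes[species]
            rep = compare(k, k)
            assert rep.chromosome_count_delta == 0
            assert rep.split_merge_groups == ()
            assert rep.translocated == () == rep.inverted == rep.repositioned

    def test_swap_symmetry_on_fixtures(self, fx):
        a, b = fx.karyotypes["Act_sp1"], fx.karyotypes["Act_sp2"]
        ab, ba = compare(a, b), compare(b, a)
        assert ab.chromosome_count_delta == -ba.chromosome_count_delta
        assert set(ab.translocated) == set(ba.translocated)
        assert set(ab.inverted) == set(ba.inverted)
        assert set(ab.repositioned) == set(ba.repositioned)

    def test_simulated_translocation_block_recovered(self):
        tree = parse_newick("(child:1.0,other:1.0);")
        root = fragmented_root()
        for seed in range(10):
            cfg = SimConfig(translocation=1.0, max_block=3, seed=seed, root_karyotype=root)
            sim = evolve_on_tree(tree, cfg, events_per_branch=1)
            ev = next(e for e in sim.events if e.branch == "child" and not e.skipped)
            rep = compare(root, sim.tips["child"])
            assert set(rep.translocated) == {g for g, _ in ev.block}

    def test_simulated_inversion_block_recovered(self):
        tree = parse_newick("(child:1.0,other:1.0);")
        root = fragmented_root()
        for seed in range(10):
            cfg = SimConfig(inversion=1.0, max_block=3, seed=seed, root_karyotype=root)
            sim = evolve_on_tree(tree, cfg, events_per_branch=1)
            ev = next(e for e in sim.events if e.branch == "child" and not e.skipped)
            rep = compare(root, sim.tips["child"])
            assert set(rep.inverted) == {g for g, _ in ev.block}
            assert rep.translocated == ()
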