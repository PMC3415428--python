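import numpy as np
import pytest

from amplocus import (
    defensin_scenario,
    lca_reconcile,
    recover_events,
    simulate_gene_family,
)
from amplocus import fixtures
from amplocus.reconcile import ReconcileError
from amplocus.seq_io import parse_newick
from oracles import brute_force_reconcile, random_binary_newick


def _rooted(newick):
    t = parse_newick(newick)
    t.is_rooted = True
    return t


class TestLcaReconcile:
    def test_congruent_trees_no_events(self):
        s = _rooted("((a:1,b:1):1,c:2);")
        g = _rooted("((a1:1,b1:1):1,c1:2);")
        res = lca_reconcile(g, s, {"a1": "a", "b1": "b", "c1": "c"})
        assert res.total_duplications == 0 and res.total_losses == 0

    def test_root_duplication_four_leaves(self):
        s = _rooted("(a:1,b:1);")
        g = _rooted("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        res = lca_reconcile(g, s, {"a1": "a", "b1": "b", "a2": "a", "b2": "b"})
        assert res.total_duplications == 1 and res.total_losses == 0
        (dup,) = res.duplication_nodes()
        assert res.node_map[dup] is s.seed_node

    def test_unmapped_leaf_rejected(self):
        s = _rooted("(a:1,b:1);")
        g = _rooted("(a1:1,b1:1);")
        with pytest.raises(ReconcileError):
            lca_reconcile(g, s, {"a1": "a"})

    def test_polytomy_rejected(self):
        s = _rooted("(a:1,b:1,c:1);")
        g = _rooted("((a1:1,b1:1):1,c1:1);")
        with pytest.raises(ReconcileError):
            lca_reconcile(g, s, {"a1": "a", "b1": "b", "c1": "c"})

    def test_matches_brute_force_minimizer(self):
        rng = np.random.default_rng(909)
        for _ in range(30):
            n_sp = int(rng.integers(2, 5))
            sp_labels = [chr(ord("a") + i) for i in range(n_sp)]
            s = _rooted(random_binary_newick(rng, sp_labels))
            n_genes = int(rng.integers(2, 7))
            gene_labels = [f"g{i}" for i in range(n_genes)]
            g = _rooted(random_binary_newick(rng, gene_labels))
            leaf_map = {
                gl: sp_labels[int(rng.integers(n_sp))] for gl in gene_labels
            }
            res = lca_reconcile(g, s, leaf_map)
            best_dups, best_losses = brute_force_reconcile(g, s, leaf_map)
            assert res.total_duplications == best_dups
            assert res.total_losses == best_losses


SPECIES_NEWICK = "((A:1.0,B:1.0):0.5,(C:0.7,(D:0.4,E:0.4):0.3):0.8);"


class TestRecoverEvents:
    def test_loss_free_recovery_is_exact(self):
        stree = _rooted(SPECIES_NEWICK)
        for seed in range(50):
            sim = simulate_gene_family(stree, 0.3, 0.0, seed=seed)
            rep = recover_events(sim)
            assert rep["inferred_duplications"] == rep["true_duplications"]
            assert rep["inferred_losses"] == 0

    def test_no_duplication_rate_no_inferred_duplications(self):
        stree = _rooted(SPECIES_NEWICK)
        for seed in range(20):
            sim = simulate_gene_family(stree, 0.0, 0.5, seed=seed)
            assert recover_events(sim)["inferred_duplications"] == 0

    def test_parsimony_lower_bound_with_losses(self):
        stree = _rooted(SPECIES_NEWICK)
        for seed in range(50):
            sim = simulate_gene_family(stree, 0.3, 0.3, seed=seed)
            rep = recover_events(sim)
            assert rep["inferred_duplications"] <= rep["true_duplications"]


class TestDefensinScenario:
    def test_duplication_placed_at_root_lca(self):
        scen = defensin_scenario()
        res = scen["result"]
        assert res.total_duplications == 1
        (dup,) = res.duplication_nodes()
        species_root = fixtures.defensin_species_tree()
        # image of the duplication covers every species (bee + all ants)
        (image,) = scen["duplication_images"]
        assert set(image) == set(fixtures.SPECIES)

    def test_single_copy_species_each_lose_a_copy(self):
        scen = defensin_scenario()
        two_copy = {"Cflo", "Sinv", "Amel"}
        for sp in fixtures.SPECIES:
            if sp in two_copy:
                assert scen["leaf_losses"][sp] == 0
            else:
                assert scen["leaf_losses"][sp] >= 1

    def test_single_paralog_gene_tree_has_no_duplication(self):
        gtree = fixtures.defensin_gene_tree()
        # prune the defensin-2 clade: the remaining tree is congruent
        keep = [
            l.taxon for l in gtree.leaf_node_iter()
            if l.taxon.label.endswith("_def1")
        ]
        gtree.retain_taxa(keep)
        scen = defensin_scenario(gene_tree=gtree)
        assert scen["result"].total_duplications == 0
        assert scen["result"].total_losses == 0

    def test_matches_brute_force_on_fixture(self):
        g = fixtures.defensin_gene_tree()
        s = fixtures.defensin_species_tree()
        res = lca_reconcile(g, s, fixtures.defensin_leaf_map())
        dups, losses = brute_force_reconcile(g, s, fixtures.defensin_leaf_map())
        assert (res.total_duplications, res.total_losses) == (dups, losses)

    def test_deleting_a_leaf_never_increases_duplications(self):
        base = defensin_scenario()["result"].total_duplications
        full = fixtures.defensin_gene_tree()
        for leaf in list(full.leaf_node_iter()):
            g = fixtures.defensin_gene_tree()
            g.retain_taxa(
                [l.taxon for l in g.leaf_node_iter()
                 if l.taxon.label != leaf.taxon.label]
            )
            scen = defensin_scenario(gene_tree=g)
            assert scen["result"].total_duplications <= base
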