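import math

import numpy as np
import pytest

from amplocus import (
    Alignment,
    DistanceMatrix,
    bootstrap_support,
    clean_blocks,
    collapse_low_support,
    distance_matrix,
    nj_tree,
    pairwise_align,
    progressive_msa,
)
from amplocus.phylo import (
    BlockCleaningError,
    SaturatedDistanceError,
    is_clade,
    tree_splits,
)
from amplocus.seq_io import ProtSeq, parse_newick
from oracles import (
    brute_force_align_score,
    mutate_protein,
    random_binary_newick,
    random_protein,
)


def _blosum62():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    return lambda a, b: float(mat[a, b])


class TestPairwiseAlign:
    def test_identical_sequences_score_is_diagonal_sum(self):
        sub = _blosum62()
        seq = "MGWFCHKLQD"
        aln, score = pairwise_align(seq, seq, kind="protein")
        assert aln.rows[0] == aln.rows[1] == seq
        assert score == pytest.approx(sum(sub(c, c) for c in seq))

    def test_empty_vs_single_residue_costs_one_gap(self):
        aln, score = pairwise_align("A", "", kind="nucleotide")
        assert score == pytest.approx(-10.5)
        assert aln.rows == ("A", "-")

    def test_matches_exhaustive_oracle_on_short_pairs(self):
        sub = _blosum62()
        rng = np.random.default_rng(606)
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(1, 7)))
            b = random_protein(rng, int(rng.integers(0, 7)))
            _, score = pairwise_align(a, b, kind="protein")
            expected = brute_force_align_score(a, b, sub, 10.0, 0.5)
            assert score == pytest.approx(expected)


class TestProgressiveMsa:
    def test_identical_sequences_align_without_gaps(self, hym_spec, hym_bundle):
        from amplocus import mature_peptides

        peps = mature_peptides(hym_bundle.protein_seq, hym_spec)[1:]
        seqs = [ProtSeq(f"HD{i}", p.sequence) for i, p in enumerate(peps, 1)]
        aln = progressive_msa(seqs)
        assert all("-" not in row for row in aln.rows)
        assert aln.n_columns == 97

    def test_substitution_only_divergence_keeps_columns_homologous(
        self, hym_bundle, hym_spec
    ):
        from amplocus import diverge_domains, mature_peptides

        div = diverge_domains(hym_bundle, 0.05, 42)
        peps = mature_peptides(div.protein_seq, hym_spec)[1:]
        seqs = [ProtSeq(f"HD{i}", p.sequence) for i, p in enumerate(peps, 1)]
        aln = progressive_msa(seqs)
        # same length, substitution-only: optimal alignment has no gaps, so
        # column i holds residue i of every domain
        assert all("-" not in row for row in aln.rows)
        for i, row in enumerate(aln.rows):
            assert row == seqs[i].seq

    def test_input_order_invariance(self, rng):
        seqs = [ProtSeq(f"s{i}", random_protein(rng, 40)) for i in range(5)]
        aln1 = progressive_msa(seqs)
        aln2 = progressive_msa(list(reversed(seqs)))
        cols1 = sorted(
            tuple(sorted(zip(aln1.ids, aln1.column(j)))) for j in range(aln1.n_columns)
        )
        cols2 = sorted(
            tuple(sorted(zip(aln2.ids, aln2.column(j)))) for j in range(aln2.n_columns)
        )
        assert cols1 == cols2


class TestCleanBlocks:
    def test_gap_free_identical_rows_unchanged(self):
        aln = Alignment(("a", "b"), ("MGWFCHKLQD", "MGWFCHKLQD"), "protein")
        out = clean_blocks(aln)
        assert out.rows == aln.rows

    def test_gappy_column_removed_and_runs_split(self):
        # 12 conserved columns with a 60%-gap column in the middle; with
        # min_block 5 both flanks survive, the gap column does not
        rows = []
        for r in range(5):
            left = "MGWFCH"
            right = "KLQDEA"
            mid = "-" if r < 3 else "W"
            rows.append(left + mid + right)
        aln = Alignment(tuple(f"s{i}" for i in range(5)), tuple(rows), "protein")
        out = clean_blocks(aln, min_block=5)
        assert out.n_columns == 12
        assert all("-" not in row for row in out.rows)

    def test_monotone_column_count(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 6))
            width = int(rng.integers(6, 40))
            rows = tuple(random_protein(rng, width) for _ in range(n))
            aln = Alignment(tuple(f"s{i}" for i in range(n)), rows, "protein")
            try:
                out = clean_blocks(aln)
            except BlockCleaningError:
                continue
            assert out.n_columns <= aln.n_columns

    def test_everything_removed_is_error(self):
        aln = Alignment(("a", "b"), ("MGW", "AQP"), "protein")
        with pytest.raises(BlockCleaningError):
            clean_blocks(aln)


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        aln = Alignment(("a", "b"), ("MGWF", "MGWF"), "protein")
        d = distance_matrix(aln)
        assert d.values.sum() == 0

    def test_closed_form_p_and_poisson(self):
        aln = Alignment(("a", "b"), ("AAAAAAAAAA", "AAAAAAAACC"), "protein")
        assert distance_matrix(aln, "p").get("a", "b") == pytest.approx(0.2)
        assert distance_matrix(aln, "poisson").get("a", "b") == pytest.approx(
            -math.log(0.8)
        )

    def test_pairwise_deletion_of_gapped_sites(self):
        aln = Alignment(("a", "b"), ("MG-WF", "MGQW-"), "protein")
        # compared sites: M, G, W -> p = 0
        assert distance_matrix(aln, "p").get("a", "b") == 0

    def test_saturated_poisson_is_error(self):
        aln = Alignment(("a", "b"), ("AAAA", "CCCC"), "protein")
        with pytest.raises(SaturatedDistanceError):
            distance_matrix(aln, "poisson")

    def test_symmetry_invariant(self, rng):
        rows = tuple(random_protein(rng, 30) for _ in range(5))
        aln = Alignment(tuple(f"s{i}" for i in range(5)), rows, "protein")
        d = distance_matrix(aln).values
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


def _additive_case(rng, n_leaves):
    labels = [f"t{i}" for i in range(n_leaves)]
    newick = random_binary_newick(rng, labels)
    tree = parse_newick(newick)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    mat = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                mat[i, j] = pdm.distance(taxa[a], taxa[b])
    return tree, DistanceMatrix(tuple(labels), mat)


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(("a", "b", "c"), np.array(
            [[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]]
        ))
        tree = nj_tree(d)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    @pytest.mark.parametrize("variant", ["nj", "bionj"])
    def test_additive_matrix_recovery(self, variant):
        rng = np.random.default_rng(707)
        for _ in range(30):
            n = int(rng.integers(5, 9))
            true_tree, d = _additive_case(rng, n)
            est = nj_tree(d, variant=variant)
            assert tree_splits(est) == tree_splits(true_tree)

    def test_equidistant_four_taxa_deterministic_tie_break(self):
        d = DistanceMatrix(
            ("a", "b", "c", "d"), np.ones((4, 4)) - np.eye(4)
        )
        tree = nj_tree(d)
        # lexicographic pair (a,b) joined first
        assert is_clade(tree, {"a", "b"})

    def test_agreement_with_independent_nj_implementation(self):
        import skbio

        rng = np.random.default_rng(808)
        for _ in range(10):
            n = int(rng.integers(5, 8))
            _, d = _additive_case(rng, n)
            mine = nj_tree(d, variant="nj")
            sk = skbio.tree.nj(
                skbio.DistanceMatrix(d.values, ids=list(d.labels))
            )
            sk_tree = parse_newick(str(sk))
            assert tree_splits(mine) == tree_splits(sk_tree)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0, 1.0], [2.0, 0]]))


def _two_clade_seqs(rng, n_sites=300):
    root = random_protein(rng, n_sites)
    left_anc = mutate_protein(rng, root, 0.15)
    right_anc = mutate_protein(rng, root, 0.15)
    seqs = []
    for i in range(3):
        seqs.append(ProtSeq(f"L{i}", mutate_protein(rng, left_anc, 0.01)))
    for i in range(3):
        seqs.append(ProtSeq(f"R{i}", mutate_protein(rng, right_anc, 0.01)))
    return seqs


class TestBootstrap:
    def test_deterministic_for_fixed_seed(self, rng):
        seqs = [ProtSeq(f"s{i}", random_protein(rng, 60)) for i in range(5)]
        t1 = bootstrap_support(seqs, n_reps=30, seed=9)
        t2 = bootstrap_support(seqs, n_reps=30, seed=9)
        assert t1.bootstrap_supports == t2.bootstrap_supports

    def test_separated_clades_get_high_support(self):
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            seqs = _two_clade_seqs(rng)
            tree = bootstrap_support(seqs, n_reps=100, seed=seed)
            split = frozenset({"R0", "R1", "R2"})
            assert split in tree.bootstrap_supports
            assert tree.bootstrap_supports[split] >= 95

    def test_supports_bounded(self, rng):
        seqs = [ProtSeq(f"s{i}", random_protein(rng, 60)) for i in range(6)]
        tree = bootstrap_support(seqs, n_reps=25, seed=3)
        assert all(0 <= v <= 100 for v in tree.bootstrap_supports.values())


class TestCollapse:
    def test_all_supports_above_threshold_unchanged(self):
        tree = parse_newick("((a:1,b:1)90:1,(c:1,d:1)85:1,e:2);")
        before = tree_splits(tree)
        assert tree_splits(collapse_low_support(tree, 40)) == before

    def test_low_support_fully_collapses_to_star(self):
        tree = parse_newick("((a:1,b:1)10:1,(c:1,d:1)20:1,e:2);")
        out = collapse_low_support(tree, 40)
        assert tree_splits(out) == set()
        assert len(list(out.leaf_node_iter())) == 5

    def test_contracted_length_moves_to_children(self):
        tree = parse_newick("((a:1,b:1)10:2,c:1,d:1);")
        out = collapse_low_support(tree, 40)
        lengths = {l.taxon.label: l.edge.length for l in out.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(3.0)
        assert lengths["b"] == pytest.approx(3.0)

    def test_split_set_monotone(self, rng):
        seqs = [ProtSeq(f"s{i}", random_protein(rng, 40)) for i in range(6)]
        tree = bootstrap_support(seqs, n_reps=30, seed=2)
        before = tree_splits(tree)
        after = tree_splits(collapse_low_support(tree, 60))
        assert after <= before
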