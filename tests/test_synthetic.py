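import numpy as np
import pytest

from amplocus import (
    ArchitectureSpec,
    IntronPlacement,
    SpecError,
    diverge_domains,
    generate_defensin_locus,
    generate_precursor_locus,
    hymenoptaecin_spec,
    simulate_gene_family,
    translate,
)
from amplocus.seq_io import parse_newick
from amplocus.synthetic import random_architecture


class TestPrecursorLocus:
    def test_default_dimensions(self, hym_spec, hym_bundle):
        assert hym_spec.protein_length == 775
        assert len(hym_bundle.protein_seq) == 775
        assert len(hym_bundle.cdna_seq) == 2536
        assert len(hym_bundle.genomic_seq) == 3356

    def test_repeat_unit_is_309_nt(self, hym_spec, hym_bundle):
        # 3 x (|EAEP| + 97 + |RR|) = 3 x 103
        assert hym_spec.repeat_unit_nt == 309
        unit = hym_bundle.cdna_seq
        segs = hym_bundle.truth_annotation.by_role("spacer")
        cs = hym_bundle.truth_gene_model.cds_start_on_cdna
        first = cs - 1 + 3 * (segs[0].start - 1)
        second = cs - 1 + 3 * (segs[1].start - 1)
        assert second - first == 309
        # exact tandem copies on the cDNA
        assert unit[first : first + 309] == unit[second : second + 309]

    def test_protein_layout(self, hym_spec, hym_bundle):
        p = hym_bundle.protein_seq
        s, pr = hym_spec.signal_len, hym_spec.pro_len
        assert p[s + pr : s + pr + 2] == "RR"
        hld = p[s + pr + 2 : s + pr + 2 + 108]
        assert hld[0] == "G" and p[s + pr + 2 + 108 : s + pr + 4 + 108] == "RR"
        base = s + pr + 2 + 108 + 2
        for r in range(6):
            unit = p[base + r * 103 : base + (r + 1) * 103]
            assert unit[:4] == "EAEP" and unit[4] == "Q" and unit[-2:] == "RR"

    def test_codon_39_is_histidine(self, hym_bundle):
        assert hym_bundle.protein_seq[38] == "H"

    def test_no_repeats_case(self):
        spec = ArchitectureSpec(n_repeats=0, introns=(), fixed_residues=())
        b = generate_precursor_locus(spec, 5)
        assert len(b.protein_seq) == 19 + 26 + 2 + 108 + 2
        assert b.truth_annotation.n_hd == 0

    def test_same_seed_byte_identical(self, hym_spec):
        b1 = generate_precursor_locus(hym_spec, 42)
        b2 = generate_precursor_locus(hym_spec, 42)
        assert b1 == b2

    def test_different_seed_same_truth_dimensions(self, hym_spec):
        b1 = generate_precursor_locus(hym_spec, 1)
        b2 = generate_precursor_locus(hym_spec, 2)
        assert b1.protein_seq != b2.protein_seq
        assert b1.truth_gene_model == b2.truth_gene_model
        assert b1.truth_annotation.segments == b2.truth_annotation.segments

    def test_intron_outside_coding_region_rejected(self):
        spec = ArchitectureSpec(
            introns=(IntronPlacement(length=100, after_codon=10_000),),
            fixed_residues=(),
        )
        with pytest.raises(SpecError):
            generate_precursor_locus(spec, 0)

    def test_truth_model_splices_and_translates(self, hym_bundle):
        m = hym_bundle.truth_gene_model
        assert m.spliced(hym_bundle.genomic_seq) == hym_bundle.cdna_seq
        assert translate(hym_bundle.cds_seq).seq == hym_bundle.protein_seq

    def test_round_trip_over_random_architectures(self):
        # splice(truth introns) then translate reproduces the protein exactly
        rng = np.random.default_rng(202)
        for i in range(40):
            spec = random_architecture(rng)
            b = generate_precursor_locus(spec, int(rng.integers(2**31)))
            assert b.truth_gene_model.spliced(b.genomic_seq) == b.cdna_seq
            assert translate(b.cds_seq).seq == b.protein_seq
            assert (
                len(b.genomic_seq) - len(b.cdna_seq)
                == sum(p.length for p in spec.introns)
            )


class TestDefensinLocus:
    @pytest.mark.parametrize(
        "exons,introns,segs,expected_len",
        [
            ((64, 229, 13), (399, 360), (17, 40, 44, 1), 102),
            ((97, 194), (1043,), (18, 36, 43, 0), 97),
            ((3,), (), (1, 0, 0, 0), 1),
        ],
    )
    def test_printed_dimensions(self, exons, introns, segs, expected_len):
        b = generate_defensin_locus(exons, introns, segs, seed=3)
        assert len(b.protein_seq) == expected_len
        assert b.truth_gene_model.intron_lengths == tuple(introns)
        assert b.truth_gene_model.cds_exon_lengths == tuple(exons)

    def test_non_divisible_coding_length_rejected(self):
        with pytest.raises(SpecError):
            generate_defensin_locus((64, 229, 14), (399, 360), (17, 40, 44, 1), 0)

    def test_segment_sum_mismatch_rejected(self):
        with pytest.raises(SpecError):
            generate_defensin_locus((64, 229, 13), (399, 360), (17, 40, 44, 0), 0)


class TestDivergeDomains:
    def test_rate_zero_is_identity(self, hym_bundle):
        div = diverge_domains(hym_bundle, 0.0, 99)
        assert div.cdna_seq == hym_bundle.cdna_seq
        assert div.genomic_seq == hym_bundle.genomic_seq
        assert div.protein_seq == hym_bundle.protein_seq

    def test_motif_columns_preserved(self, hym_spec, hym_bundle):
        div = diverge_domains(hym_bundle, 0.2, 7)
        p = div.protein_seq
        for seg in div.truth_annotation.by_role("spacer"):
            assert p[seg.start - 1 : seg.end] == "EAEP"
        for seg in div.truth_annotation.by_role("cleavage"):
            assert p[seg.start - 1 : seg.end] == "RR"

    def test_mean_pairwise_identity_at_rate_005(self, hym_spec):
        # 20 seeds; direct identity computation on generated output
        idents = []
        for seed in range(20):
            b = generate_precursor_locus(hym_spec, seed)
            div = diverge_domains(b, 0.05, seed + 1000)
            cs = div.truth_gene_model.cds_start_on_cdna - 1
            frags = []
            for seg in div.truth_annotation.by_role("HD"):
                lo = cs + 3 * (seg.start - 1)
                hi = cs + 3 * seg.end
                frags.append(div.cdna_seq[lo:hi])
            for i in range(len(frags)):
                for j in range(i + 1, len(frags)):
                    same = sum(a == b_ for a, b_ in zip(frags[i], frags[j]))
                    idents.append(same / len(frags[i]))
        mean = sum(idents) / len(idents)
        assert 0.8 < mean < 1.0

    def test_truth_records_unchanged(self, hym_bundle):
        div = diverge_domains(hym_bundle, 0.1, 3)
        assert div.truth_gene_model == hym_bundle.truth_gene_model
        assert div.truth_annotation.segments == hym_bundle.truth_annotation.segments
        assert div.truth_gene_model.spliced(div.genomic_seq) == div.cdna_seq
        assert translate(div.cds_seq).seq == div.protein_seq


SPECIES_NEWICK = "((A:1.0,B:1.0):0.5,(C:0.7,(D:0.4,E:0.4):0.3):0.8);"


def _species_tree():
    t = parse_newick(SPECIES_NEWICK)
    t.is_rooted = True
    return t


class TestGeneFamilySim:
    def test_zero_rates_congruent_with_species_tree(self):
        sim = simulate_gene_family(_species_tree(), 0.0, 0.0, seed=1)
        assert sim.true_duplications == 0 and sim.true_losses == 0
        leaves = sorted(sim.leaf_to_species.values())
        assert leaves == ["A", "B", "C", "D", "E"]
        from amplocus.phylo import tree_splits

        # relabel gene leaves by species and compare split sets
        for leaf in sim.gene_tree.leaf_node_iter():
            leaf.taxon.label = sim.leaf_to_species[leaf.taxon.label]
        assert tree_splits(sim.gene_tree) == tree_splits(_species_tree())

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_family(_species_tree(), -0.1, 0.0, seed=0)

    def test_same_seed_identical(self):
        s1 = simulate_gene_family(_species_tree(), 0.4, 0.2, seed=7)
        s2 = simulate_gene_family(_species_tree(), 0.4, 0.2, seed=7)
        assert s1.true_duplications == s2.true_duplications
        assert s1.true_losses == s2.true_losses
        assert s1.gene_tree.as_string(schema="newick") == s2.gene_tree.as_string(
            schema="newick"
        )
        assert s1.leaf_to_species == s2.leaf_to_species

    def test_mean_duplications_match_monte_carlo_expectation(self):
        # branch-length-weighted expectation estimated with 10x replicates
        dup_rate = 0.3
        main = [
            simulate_gene_family(_species_tree(), dup_rate, 0.0, seed=s)
            .true_duplications
            for s in range(200)
        ]
        ref = [
            simulate_gene_family(_species_tree(), dup_rate, 0.0, seed=10_000 + s)
            .true_duplications
            for s in range(2000)
        ]
        m1, m2 = np.mean(main), np.mean(ref)
        se = np.sqrt(np.var(main) / len(main) + np.var(ref) / len(ref))
        assert abs(m1 - m2) <= 2 * se + 1e-9

    def test_extinct_families_resampled_and_reported(self):
        # loss-dominated process: some seeds must resample
        resamples = [
            simulate_gene_family(_species_tree(), 0.0, 2.0, seed=s).resample_count
            for s in range(20)
        ]
        assert all(r >= 0 for r in resamples)
        assert any(r > 0 for r in resamples)
        for s in range(20):
            sim = simulate_gene_family(_species_tree(), 0.0, 2.0, seed=s)
            assert len(sim.leaf_to_species) >= 1
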