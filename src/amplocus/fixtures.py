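"""Bundled synthetic fixture topologies for the defensin reconciliation.

The nine-taxon species tree covers the honey bee (Amel) as sister to the
ants, with a myrmicine clade (Mscab, Pbar, Sinv, Aech) and a formicine clade
(Lnig, Cflo, Faqu) plus the early-branching Hsal.  No published Newick
exists for this topology, so it is configuration: only LCA-level claims are
asserted against it, never branch-level placements.

The synthetic gene tree carries the two-paralog pattern: every species has a
defensin-1 copy (congruent with the species tree), while only Cflo and Sinv
(plus the bee) retain a defensin-2 copy.  Reconciling it places one
duplication at the root — the common ancestor of bee and ants — and one loss
on each single-copy species' branch.
"""

from __future__ import annotations

import dendropy

from .seq_io import parse_newick

SPECIES = ("Amel", "Hsal", "Mscab", "Pbar", "Sinv", "Aech", "Lnig", "Cflo", "Faqu")

DEFENSIN_SPECIES_NEWICK = (
    "(Amel:3.0,(Hsal:2.5,((Mscab:1.8,(Pbar:1.4,(Sinv:1.0,Aech:1.0):0.4):0.4):0.5,"
    "(Lnig:1.5,(Cflo:1.0,Faqu:1.0):0.5):0.8):0.2):0.5);"
)

#: synthetic gene tree (two-paralog pattern; see module docstring)
DEFENSIN_GENE_NEWICK = (
    "((Amel_def1:3.0,(Hsal_def1:2.5,((Mscab_def1:1.8,(Pbar_def1:1.4,"
    "(Sinv_def1:1.0,Aech_def1:1.0):0.4):0.4):0.5,(Lnig_def1:1.5,"
    "(Cflo_def1:1.0,Faqu_def1:1.0):0.5):0.8):0.2):0.5):0.3,"
    "(Amel_def2:3.0,(Sinv_def2:2.2,Cflo_def2:2.2):0.8):0.3);"
)


def defensin_species_tree() -> dendropy.Tree:
    tree = parse_newick(DEFENSIN_SPECIES_NEWICK)
    tree.is_rooted = True
    return tree


def defensin_gene_tree() -> dendropy.Tree:
    tree = parse_newick(DEFENSIN_GENE_NEWICK)
    tree.is_rooted = True
    return tree


def defensin_leaf_map() -> dict[str, str]:
    return {
        leaf.taxon.label: leaf.taxon.label.split("_")[0]
        for leaf in defensin_gene_tree().leaf_node_iter()
    }
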