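# amplocus

Analysis toolkit for **multipeptide antimicrobial-peptide (AMP) precursor
loci** of the kind found in ant innate immunity: a single gene encodes a
precursor with a signal peptide, a propeptide, one *hymenoptaecin-like
domain* (HLD) and several tandem-repeated *hymenoptaecin domains* (HDs),
each repeat framed by an `EAEP` spacer and a dibasic `RR`/`KR` proprotein
convertase site. Proteolytic processing of one transcript therefore
releases many mature AMPs at once. The package also models the simpler
defensin-type gene structures (two or three exons, phase-1/phase-2 introns)
and the gene-family history behind two-paralog defensin repertoires.

It is aimed at people studying insect AMP gene structure and evolution who
want every step of such an analysis as tested, seedable code — without
depending on any particular sequencing project's accessions.

## What it does

* **`amplocus.synthetic`** — generates seeded synthetic loci that carry the
  full structural grammar: precursor architecture (`ArchitectureSpec`),
  genomic/cDNA/protein bundles with ground truth (`generate_precursor_locus`,
  `generate_defensin_locus`), per-domain sequence divergence
  (`diverge_domains`) and duplication–loss gene-family simulation along a
  species tree (`simulate_gene_family`).
* **`amplocus.gene_structure`** — exact splice mapping of a cDNA onto its
  gene (`splice_map`), intron phase / interrupted-codon arithmetic
  (`intron_report`), CDS-exon protein-length arithmetic
  (`coding_protein_length`). Intron phase is the number of nucleotides of
  the interrupted codon already emitted upstream (0, 1 or 2).
* **`amplocus.precursor`** — dibasic-site scanning (`scan_cleavage_sites`)
  and grammar-based segmentation of a precursor into
  signal/pro/HLD/spacer/HD/cleavage intervals (`segment_precursor`), plus
  residue-to-cDNA interval mapping (`map_segments_to_cdna`).
* **`amplocus.maturation`** — the three-step maturation cascade:
  KEX2-like endoprotease (cuts C-terminal to `RR`/`KR`/`RK`), KEX1-like
  carboxypeptidase (removes both basic residues), dipeptidyl aminopeptidase
  (removes N-terminal E/D–A/P dipeptides), with exact residue accounting.
* **`amplocus.repeats`** — de-novo tandem repeat detection by k-mer
  self-match seeding and ungapped copy-vs-consensus extension
  (`find_tandem_repeats`), plus the PCR slippage-ladder prediction
  (`amplicon_ladder`).
* **`amplocus.phylo`** — affine-gap pairwise and progressive profile
  alignment, conserved-block cleaning, p/Poisson distances, NJ and BioNJ
  with documented tie-breaks, column-bootstrap supports and collapse of
  branches below a support threshold into polytomies.
* **`amplocus.reconcile`** — LCA duplication–loss reconciliation of a rooted
  gene tree against a rooted species tree, with per-branch loss counts and
  a bundled nine-taxon two-paralog defensin scenario
  (`defensin_scenario`).
* **`amplocus.cli`** — `amplocus` command with per-stage subcommands and a
  config-driven `run` that writes a hashed manifest (deterministic under a
  global seed).

## Worked example

```python
import amplocus as am

spec = am.hymenoptaecin_spec()          # 19/26 aa signal/pro, 108-aa HLD,
b = am.generate_precursor_locus(spec, seed=1)  # 6 x 97-aa HDs, EAEP + RR

len(b.genomic_seq), len(b.cdna_seq), len(b.protein_seq)
# (3356, 2536, 775)

m = am.splice_map(b.genomic_seq, b.cdna_seq, cds_start_on_cdna=101, cds_len=2325)
am.intron_report(m, b.protein_seq)[0]
# IntronReport(index=1, length=820, phase=0, codon=39,
#              boundary='between codons 39|40', residue='H')

[(len(p), p.n_term) for p in am.mature_peptides(b.protein_seq, spec)]
# [(108, 'G'), (97, 'Q'), (97, 'Q'), (97, 'Q'), (97, 'Q'), (97, 'Q'), (97, 'Q')]

top = am.find_tandem_repeats(b.cdna_seq)[0]
top.period, top.full_copies, top.mean_identity
# (309, 6, 1.0)
```

The gene is 3356 nt and its transcript 2536 nt: the difference is the
single 820-nt phase-0 intron, which falls cleanly between codons 39 and 40
(a histidine). Maturation releases one 108-aa glycine-initial
hymenoptaecin-like peptide and six identical 97-aa glutamine-initial
hymenoptaecin peptides (a Q N-terminus permits pyroglutamate capping), and
the repeat detector finds the underlying 309-nt tandem unit —
3 × (4 spacer + 97 domain + 2 cleavage residues) — without being told the
architecture. `am.maturation_accounting(...)` balances the books exactly:
775 residues in = 47 signal+pro + 14 trimmed basics + 24 trimmed spacer
residues + 690 peptide residues out.

For the gene-family side:

```python
scen = am.defensin_scenario()
scen["result"].total_duplications, scen["result"].total_losses
# (1, 6)
```

— one duplication at the common ancestor of the bee and the ants, and one
loss on the branch of each species that retains a single paralog.

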