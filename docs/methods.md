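# Methods

## The model

`amplocus` treats a multipeptide AMP precursor locus as a formal grammar
over residues:

```
precursor := signal  pro  CLV  HLD  CLV  (SPACER HD CLV){n}
CLV       := RR | KR | RK          (dibasic convertase site)
SPACER    := EAEP                  (E/D–A/P dipeptide ladder)
```

with a gene structure of UTR5 + CDS (+ stop codon) + UTR3 and zero or more
GT..AG introns strictly inside the CDS. Maturation is modelled as three
sequential enzymatic activities: an endoprotease cutting C-terminal to each
dibasic site, a carboxypeptidase removing the (at most two) C-terminal
basic residues of each fragment, and a dipeptidyl aminopeptidase peeling
E/D–A/P dipeptides off each fragment's N-terminus. Under this model the
spacer is removed as EA + EP, every repeat releases an identical-length
peptide whose N-terminal glutamine can cyclize to pyroglutamate, and total
residues are conserved exactly (the accounting is emitted per run and
asserted in tests).

## Default parameters

| parameter | default | unit | note |
|---|---|---|---|
| signal / pro length | 19 / 26 | aa | precursor leader segments |
| HLD length, first residue | 108, G | aa | the single long domain |
| HD length, first residue | 97, Q | aa | each repeated domain |
| repeats `n` | 6 | – | tandem copy number |
| spacer / cleavage motif | EAEP / RR | – | per repeat unit |
| intron | 820 nt, phase 0, after codon 39 | – | codon 39 fixed to His |
| UTR5 / UTR3 | 100 / 108 | nt | see below |
| repeat unit | 3×(4+97+2) = 309 | nt | derived |

The UTR lengths are the one free choice: no UTR sizes are part of the
printed architecture, so they were set once so that the default transcript
is exactly 2536 nt and the gene 3356 nt (difference = the 820-nt intron).
The stop codon is *excluded* from `GeneModel.cds_len`; the printed exon
arithmetic then satisfies `sum(CDS exons)/3 = protein length` exactly
(e.g. 64+229+13 = 306 nt = 102 aa for the three-exon defensin gene), and
the stop codon sits at the start of the 3' trailing region.

Defensin-type gene models are driven purely by printed dimensions:
exons (64, 229, 13) with introns (399, 360) give a 102-aa prepropeptide
(17 signal + 40 pro + 44 mature + 1 trailing glycine; the extra residue
reconciles the segment sum with the exon sum and mirrors the amidation
donor known from bee defensins); exons (97, 194) with a 1043-nt intron
give a 97-aa prepropeptide (18 + 36 + 43).

## What the generator emulates — and what it does not

The generator reproduces *structure*, not sequence: segment lengths,
motifs, repeat geometry, intron placement and phase. Unconstrained
residues are uniform over the 20 amino acids with two rejection rules
(no adjacent basic pair anywhere outside a cleavage motif; no basic
residue immediately before one), so the dibasic sites present are exactly
the grammar's sites and parser-vs-truth comparisons are exact. Real
precursors have amino-acid composition bias (hymenoptaecins are
glycine-rich), codon-usage bias, imperfect repeats and occasional internal
dibasic pairs; passing tests therefore demonstrate correctness of the
*algorithms* on in-grammar data, not robustness to every biological edge
case. HD repeats are emitted as exact nucleotide copies (one residue
string, one codon encoding, tiled n times); divergence among copies is
supplied separately by `diverge_domains`, which mutates HD codons at a
given per-site rate while reverting any mutation that would create a stop
codon or a spurious dibasic site (both would break model invariants; the
realized rate is marginally lower at the affected codons).

Back-translation uses uniform synonymous codon choice — no codon-usage
table is assumed. Intron interiors are uniform random between canonical
GT/AG ends. One deliberate correction keeps splice mapping exact: at each
3' splice junction the first exonic base is resampled (codon first, free
residue if necessary) so it differs from the intron's initial G. Without
this, a greedy left-to-right mapper can return a shifted model with the
same intron length — observationally equivalent, but not equal to the
recorded truth.

## Splice mapping and its scope

`splice_map` assumes the cDNA is an *exact* ordered concatenation of
genomic substrings (gene and transcript sequenced from the same clones);
mismatch- or indel-tolerant spliced alignment is explicitly out of scope.
It extends matches greedily and, at each mismatch, takes the smallest gap
at which the next 20 cDNA nucleotides resume exactly. When the remaining
cDNA is shorter than the anchor, finding more than one minimal resumption
raises an "ambiguous splice" error rather than guessing silently.

## Repeat detection

Candidate periods are offsets (30–600 nt) supported by exact 12-mer
self-matches; each candidate is extended to a maximal array by ungapped
copy-vs-consensus comparison (consensus = per-column majority, ties
alphabetical), keeping arrays with ≥ 2 copies at ≥ 0.8 mean identity.
Overlapping reports are resolved by highest copies × period, then smallest
period — this prefers the 309-nt unit over its 618/927-nt harmonics, which
tie on covered span. Partial edge copies are reported fractionally. The
copy model has no indels, matching exact-length biological repeat units;
indel-tolerant (wraparound-DP) detection is a non-goal.

## Phylogenetics

The domain-tree chain is distance-based by design: maximum-likelihood
inference is deliberately replaced with NJ/BioNJ because the claims the
package supports are topological (per-species clading of amplified
domains), not likelihood values. Numerical contracts:

* pairwise and profile alignment is global affine-gap (Gotoh), BLOSUM62
  for protein, +1/−1 for nucleotide, gap open 10 and extend 0.5 (a gap of
  length L costs 10 + 0.5·L); traceback prefers diagonal, then up, then
  left. Profile columns score as the average pairwise substitution score
  with gaps contributing zero.
* the progressive MSA merges profiles in NJ agglomeration order computed
  from k-mer set distances (k=3 protein / k=5 nucleotide); all ties break
  on lexicographic cluster keys, so the result is input-order invariant.
* block cleaning keeps maximal runs (≥ 5 columns) of columns with ≤ 50%
  gaps and a most-frequent-residue fraction ≥ 50% — a simplified,
  documented stand-in for Gblocks-style filtering.
* distances use pairwise deletion of gapped sites; the Poisson correction
  −ln(1−p) errors on saturated pairs rather than extrapolating.
* NJ/BioNJ: Q-criterion selection with lexicographic tie-breaks; negative
  branch lengths are clamped to zero with the deficit moved to the sister
  branch; BioNJ uses the standard one-parameter variance-weighted
  reduction (initial variances = distances, lambda clamped to [0, 1]).
* bootstrap resamples alignment columns (no re-alignment) and supports are
  percentages over replicates; collapsing a branch below threshold 40 adds
  its length to each child edge — how collapsed branch lengths should be
  redistributed is not otherwise specified anywhere, so this additive
  choice is documented here.

## Reconciliation

LCA mapping with the standard event rule (duplication iff a node's image
equals a child's image) and depth-difference loss counting, attributed per
species branch via the sibling-subtree rule. Species trees with polytomies
are rejected. The bundled nine-taxon fixture is configuration, not data:
its topology reflects the accepted relationships of the taxa it names, but
only LCA-level conclusions (duplication at the bee+ant ancestor; one loss
per single-copy lineage) are asserted against it. The birth–death
simulator counts every true event including those in extinct subtrees, so
inferred duplications equal true duplications only in the loss-free case
and are otherwise a parsimony lower bound — both properties are tested.

## Degenerate inputs and tie-breaks (summary)

Empty repeat counts (n = 0) are legal and release a single HLD peptide.
Dibasic runs like `RRR` resolve leftmost-pair-first. Equidistant NJ inputs
resolve lexicographically. A fragment fully consumed by trimming is
dropped with a warning. Families that go extinct in simulation are
resampled with an incremented seed and the resample count is reported.

## Problem sizes

The bundled property suites run at: 200 random architectures for the
generator↔parser round trip, 100 for splice recovery, 100 random additive
matrices (5–8 leaves) per NJ variant, 50 alignment pairs (≤ 8 residues)
against exhaustive enumeration, 100 reconciliation instances (≤ 6 leaves)
against the brute-force minimizer, 200 loss-free family simulations, and a
15-sequence end-to-end domain-amplification tree. These sizes give full
coverage of the tie-break and boundary behaviour while keeping the whole
suite under a minute on one CPU.

## Known limitations

* The parser requires the template's signal/pro lengths; it does not
  predict signal peptides.
* RXXR convertase sites are recognized only when enabled; the default
  grammar is dibasic-only.
* The dipeptidyl rule set {EA, EP, DA, DP} cannot remove an EANP-style
  spacer (the AN step is outside E/D–A/P); widen `dipeptides` explicitly
  for such variants.
* `splice_map` is exact-match only and + strand only; no alternative
  isoforms.
* Repeat detection reports substitution-diverged arrays only; indels
  within copies break the period arithmetic by design.
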