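"""Seeded synthetic loci carrying the structural grammar of multipeptide
antimicrobial-peptide precursors.

The generator emulates three kinds of object:

* a hymenoptaecin-style precursor locus — signal peptide, propeptide, one
  hymenoptaecin-like domain (HLD) and ``n`` tandem-repeated hymenoptaecin
  domains (HDs), each repeat preceded by an EAEP spacer and followed by a
  dibasic cleavage site, with a single-intron gene structure;
* defensin-style gene models defined purely by printed exon/intron sizes;
* gene families evolved by a duplication-loss birth-death process along a
  rooted species tree, for testing reconciliation.

Everything is driven by one integer seed per operation, so identical seeds
produce byte-identical bundles.  Repeat units are emitted as exact copies
(one residue string, one codon encoding, tiled ``n`` times): the tandem
array in the transcript is therefore perfect, and sequence divergence among
domains is supplied separately by :func:`diverge_domains`.

Free (unconstrained) residues are drawn uniformly from the 20 standard amino
acids with one rejection rule: no two adjacent basic residues (R/K), and no
basic residue immediately before a cleavage motif.  This guarantees that the
dibasic sites scanned downstream are exactly the sites the grammar placed —
the generator's truth and the parser's output can then be compared exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .annotations import PrecursorAnnotation, Segment
from .gene_structure import GeneModel
from .seq_io import STOP_CODONS, translate

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASIC = frozenset("RK")
DIBASIC_MOTIFS = ("RR", "KR", "RK")

#: amino acid -> sorted tuple of codons (standard genetic code)
CODONS_FOR: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS_FOR.setdefault(_aa, [])
    CODONS_FOR[_aa].append(_codon)
CODONS_FOR = {aa: tuple(sorted(cs)) for aa, cs in CODONS_FOR.items()}


class SpecError(ValueError):
    """Invalid architecture specification."""


@dataclass(frozen=True)
class IntronPlacement:
    """An intron inside the coding region.

    ``after_codon=k`` places a phase-0 intron after codon k; alternatively
    ``within_codon=k, phase=1|2`` interrupts codon k after 1 or 2 of its
    nucleotides.  ``length`` is the full intron length in nt including the
    canonical GT..AG ends.
    """

    length: int
    after_codon: int | None = None
    within_codon: int | None = None
    phase: int = 0

    def __post_init__(self):
        if self.length < 4:
            raise SpecError("intron length must be at least 4 (GT..AG)")
        if (self.after_codon is None) == (self.within_codon is None):
            raise SpecError("specify exactly one of after_codon / within_codon")
        if self.after_codon is not None:
            if self.after_codon < 1:
                raise SpecError("after_codon must be >= 1")
            if self.phase != 0:
                raise SpecError("after_codon placements are phase 0")
        else:
            if self.within_codon < 1 or self.phase not in (1, 2):
                raise SpecError("within_codon placements need phase 1 or 2")

    @property
    def coding_offset(self) -> int:
        """Coding nucleotides upstream of the intron (0-based insertion point)."""
        if self.after_codon is not None:
            return 3 * self.after_codon
        return 3 * (self.within_codon - 1) + self.phase


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of a multipeptide precursor locus.

    Defaults describe the hymenoptaecin architecture: 19-aa signal, 26-aa
    pro, 108-aa G-initial HLD, six 97-aa Q-initial HDs each preceded by an
    EAEP spacer and followed by an RR site, one 820-nt phase-0 intron after
    codon 39 (fixed to histidine), UTRs sized so that the cDNA is 2536 nt
    and the gene 3356 nt.
    """

    signal_len: int = 19
    pro_len: int = 26
    hld_len: int = 108
    hd_len: int = 97
    n_repeats: int = 6
    spacer_motif: str = "EAEP"
    cleavage_motif: str = "RR"
    hld_first_residue: str = "G"
    hd_first_residue: str = "Q"
    introns: tuple[IntronPlacement, ...] = (
        IntronPlacement(length=820, after_codon=39),
    )
    utr5_len: int = 100
    utr3_len: int = 108
    #: residue overrides in the free signal+pro stretch, ((1-based pos, aa), ...)
    fixed_residues: tuple[tuple[int, str], ...] = ((39, "H"),)

    # -- derived arithmetic --------------------------------------------------

    @property
    def repeat_unit_aa(self) -> int:
        return len(self.spacer_motif) + self.hd_len + len(self.cleavage_motif)

    @property
    def repeat_unit_nt(self) -> int:
        return 3 * self.repeat_unit_aa

    @property
    def protein_length(self) -> int:
        cm = len(self.cleavage_motif)
        return (
            self.signal_len
            + self.pro_len
            + cm
            + self.hld_len
            + cm
            + self.n_repeats * self.repeat_unit_aa
        )

    @property
    def cds_len(self) -> int:
        """Coding nucleotides, stop codon excluded."""
        return 3 * self.protein_length

    def validate(self) -> None:
        for name in ("signal_len", "pro_len", "hld_len", "hd_len"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if self.n_repeats < 0:
            raise SpecError("n_repeats must be >= 0")
        if self.cleavage_motif not in DIBASIC_MOTIFS:
            raise SpecError(
                f"cleavage_motif must be one of {DIBASIC_MOTIFS}, "
                f"got {self.cleavage_motif!r}"
            )
        if not self.spacer_motif or set(self.spacer_motif) - set(AMINO_ACIDS):
            raise SpecError(f"bad spacer motif {self.spacer_motif!r}")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise SpecError("UTR lengths must be >= 0")
        offsets = [p.coding_offset for p in self.introns]
        if len(set(offsets)) != len(offsets):
            raise SpecError("intron placements overlap")
        for off in offsets:
            if not (1 <= off <= self.cds_len - 1):
                raise SpecError(
                    f"intron placement at coding offset {off} falls outside the "
                    f"coding region (1..{self.cds_len - 1})"
                )
        free_end = self.signal_len + self.pro_len
        for pos, aa in self.fixed_residues:
            if not (1 <= pos <= free_end):
                raise SpecError(
                    f"fixed residue at {pos} outside the free signal+pro stretch"
                )
            if aa not in AMINO_ACIDS:
                raise SpecError(f"fixed residue {aa!r} is not a standard amino acid")


def hymenoptaecin_spec() -> ArchitectureSpec:
    """The default hymenoptaecin precursor architecture (all printed dims)."""
    return ArchitectureSpec()


#: printed defensin gene dimensions: (exon_lengths, intron_lengths, segment_lens)
#: segment_lens = (signal, pro, mature, extra C-terminal residues)
DEFENSIN1_DIMS = ((64, 229, 13), (399, 360), (17, 40, 44, 1))
DEFENSIN2_DIMS = ((97, 194), (1043,), (18, 36, 43, 0))


@dataclass(frozen=True)
class LocusBundle:
    """A generated locus with its ground truth."""

    genomic_seq: str
    cdna_seq: str
    protein_seq: str
    truth_gene_model: GeneModel
    truth_annotation: PrecursorAnnotation
    seed: int
    spec: ArchitectureSpec | None = None

    @property
    def cds_seq(self) -> str:
        m = self.truth_gene_model
        return self.cdna_seq[m.cds_start_on_cdna - 1 : m.cds_start_on_cdna - 1 + m.cds_len]


# ---------------------------------------------------------------------------
# residue / codon drawing helpers
# ---------------------------------------------------------------------------

def _draw_free(rng, length, *, first=None, prev=None, fixed=None,
               last_not_basic=True) -> list[str]:
    """Draw a free residue stretch, rejecting adjacent basic pairs."""
    out: list[str] = []
    fixed = fixed or {}
    for idx in range(length):
        if (idx + 1) in fixed:
            res = fixed[idx + 1]
        elif idx == 0 and first is not None:
            res = first
        else:
            before = out[-1] if out else prev
            while True:
                res = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
                if before in BASIC and res in BASIC:
                    continue
                if last_not_basic and idx == length - 1 and res in BASIC:
                    continue
                break
        out.append(res)
    # fixed overrides may not break the adjacency rules
    for idx in range(length):
        here = out[idx]
        before = out[idx - 1] if idx else prev
        if before in BASIC and here in BASIC:
            raise SpecError(
                f"fixed residue creates an adjacent basic pair at stretch index {idx + 1}"
            )
    if last_not_basic and out and out[-1] in BASIC:
        raise SpecError("fixed residue places a basic residue before a cleavage motif")
    return out


def _rand_nt(rng, length: int) -> str:
    return "".join("ACGT"[int(i)] for i in rng.integers(4, size=length))


def _draw_codons(rng, residues: Sequence[str]) -> list[str]:
    return [
        CODONS_FOR[aa][int(rng.integers(len(CODONS_FOR[aa])))] for aa in residues
    ]


def _escape_codons(aa: str, offset: int) -> tuple[str, ...]:
    """Codons for ``aa`` whose base at ``offset`` is not G (splice-site escape)."""
    return tuple(c for c in CODONS_FOR[aa] if c[offset] != "G")


# ---------------------------------------------------------------------------
# precursor locus
# ---------------------------------------------------------------------------

def generate_precursor_locus(spec: ArchitectureSpec, seed: int) -> LocusBundle:
    """Generate a precursor locus (genomic, cDNA, protein + truth records).

    Protein layout: signal + pro + cleavage + HLD + cleavage +
    n_repeats x (spacer + HD + cleavage).  The coding DNA is back-translated
    with seeded uniform synonymous codon choice; introns are inserted with
    canonical GT..AG ends.  At every 3' splice junction the first exonic base
    is kept distinct from G (resampling the codon, or the free residue) so the
    greedy splice mapper recovers the truth model exactly rather than a
    shifted equivalent.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    cm, sp = spec.cleavage_motif, spec.spacer_motif
    s, p = spec.signal_len, spec.pro_len

    fixed = dict(spec.fixed_residues)
    prefix = _draw_free(rng, s + p, fixed=fixed)
    hld = _draw_free(rng, spec.hld_len, first=spec.hld_first_residue, prev=cm[-1])
    hd = _draw_free(rng, spec.hd_len, first=spec.hd_first_residue, prev=cm[-1])

    # codon slots; the repeat unit is encoded once and tiled
    slot_res = {
        "prefix": prefix,
        "cm1": list(cm),
        "hld": hld,
        "cm2": list(cm),
        "unit": list(sp) + hd + list(cm),
    }
    slot_cod = {name: _draw_codons(rng, res) for name, res in slot_res.items()}

    L0 = s + p
    L1 = L0 + len(cm)
    L2 = L1 + spec.hld_len
    L3 = L2 + len(cm)
    unit_aa = spec.repeat_unit_aa

    def locate(q: int) -> tuple[str, int]:
        if q < L0:
            return "prefix", q
        if q < L1:
            return "cm1", q - L0
        if q < L2:
            return "hld", q - L1
        if q < L3:
            return "cm2", q - L2
        return "unit", (q - L3) % unit_aa

    def is_free(slot: str, loc: int) -> bool:
        if slot == "prefix":
            return (loc + 1) not in fixed
        if slot == "hld":
            return loc > 0 and loc < spec.hld_len - 1
        if slot == "unit":
            hd_lo = len(sp)
            hd_hi = len(sp) + spec.hd_len
            return hd_lo + 1 <= loc < hd_hi - 1
        return False

    # splice-junction identifiability (see docstring)
    for placement in sorted(spec.introns, key=lambda x: x.coding_offset):
        cpos = placement.coding_offset
        q, o = cpos // 3, cpos % 3
        slot, loc = locate(q)
        aa = slot_res[slot][loc]
        allowed = _escape_codons(aa, o)
        if allowed:
            if slot_cod[slot][loc] not in allowed:
                slot_cod[slot][loc] = allowed[int(rng.integers(len(allowed)))]
            continue
        if not is_free(slot, loc):
            raise SpecError(
                f"intron at coding offset {cpos} cannot be made splice-identifiable: "
                f"residue {aa!r} at codon {q + 1} is constrained and every codon "
                f"starts the downstream exon with G"
            )
        neighbours = []
        for dq in (-1, 1):
            ns, nl = locate(q + dq) if 0 <= q + dq < spec.protein_length else (None, None)
            neighbours.append(slot_res[ns][nl] if ns else None)
        choices = [
            a
            for a in AMINO_ACIDS
            if _escape_codons(a, o)
            and not (a in BASIC and any(n in BASIC for n in neighbours))
        ]
        new_aa = choices[int(rng.integers(len(choices)))]
        slot_res[slot][loc] = new_aa
        esc = _escape_codons(new_aa, o)
        slot_cod[slot][loc] = esc[int(rng.integers(len(esc)))]

    prefix = slot_res["prefix"]
    hld = slot_res["hld"]
    protein = (
        "".join(prefix)
        + cm
        + "".join(hld)
        + cm
        + "".join(slot_res["unit"]) * spec.n_repeats
    )
    cds = (
        "".join(slot_cod["prefix"])
        + "".join(slot_cod["cm1"])
        + "".join(slot_cod["hld"])
        + "".join(slot_cod["cm2"])
        + "".join(slot_cod["unit"]) * spec.n_repeats
    )
    stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
    utr5 = _rand_nt(rng, spec.utr5_len)
    utr3 = _rand_nt(rng, spec.utr3_len)
    cdna = utr5 + cds + stop + utr3

    placements = sorted(spec.introns, key=lambda x: x.coding_offset)
    intron_seqs = [
        "GT" + _rand_nt(rng, pl.length - 4) + "AG" for pl in placements
    ]

    genomic_parts = [utr5]
    exons = []
    g_cursor = 0  # genomic length emitted so far
    t_cursor = 0  # transcript position at last exon boundary
    prev_cut = 0
    for pl, iseq in zip(placements, intron_seqs):
        cut = pl.coding_offset
        exon_piece = cds[prev_cut:cut]
        genomic_parts.append(exon_piece)
        exon_len = len(utr5) + len(exon_piece) if not exons else len(exon_piece)
        exons.append((g_cursor + 1, g_cursor + exon_len))
        g_cursor += exon_len
        genomic_parts.append(iseq)
        g_cursor += len(iseq)
        prev_cut = cut
    tail = cds[prev_cut:] + stop + utr3
    genomic_parts.append(tail)
    tail_len = len(tail) if exons else len(utr5) + len(tail)
    exons.append((g_cursor + 1, g_cursor + tail_len))
    genomic = "".join(genomic_parts)

    model = GeneModel(
        exons=tuple(exons),
        cds_start_on_cdna=spec.utr5_len + 1,
        cds_len=spec.cds_len,
    )

    segments = [
        Segment("signal", 1, s),
        Segment("pro", s + 1, s + p),
        Segment("cleavage", L0 + 1, L1),
        Segment("HLD", L1 + 1, L2),
        Segment("cleavage", L2 + 1, L3),
    ]
    for r in range(spec.n_repeats):
        base = L3 + r * unit_aa
        segments.append(Segment("spacer", base + 1, base + len(sp)))
        segments.append(Segment("HD", base + len(sp) + 1, base + len(sp) + spec.hd_len))
        segments.append(
            Segment("cleavage", base + len(sp) + spec.hd_len + 1, base + unit_aa)
        )
    annotation = PrecursorAnnotation(segments=tuple(segments))

    bundle = LocusBundle(
        genomic_seq=genomic,
        cdna_seq=cdna,
        protein_seq=protein,
        truth_gene_model=model,
        truth_annotation=annotation,
        seed=seed,
        spec=spec,
    )
    _check_bundle(bundle)
    return bundle


def _check_bundle(bundle: LocusBundle) -> None:
    """Generator post-conditions: splicing and translation round-trip."""
    model = bundle.truth_gene_model
    if model.spliced(bundle.genomic_seq) != bundle.cdna_seq:
        raise AssertionError("truth model does not splice genomic into cDNA")
    prot = translate(bundle.cds_seq).seq
    if prot != bundle.protein_seq:
        raise AssertionError("CDS does not translate to the recorded protein")


# ---------------------------------------------------------------------------
# defensin-style locus
# ---------------------------------------------------------------------------

def generate_defensin_locus(
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
    segment_lens: Sequence[int],
    seed: int,
    utr5_len: int = 0,
    utr3_len: int = 0,
) -> LocusBundle:
    """Generate a defensin-type locus from printed exon/intron sizes.

    ``exon_lengths`` are CDS exon sizes (stop codon excluded; one is appended
    after the CDS).  ``segment_lens`` = (signal, pro, mature, extra C-terminal
    residues) and must sum to the implied protein length.
    """
    exon_lengths = tuple(int(x) for x in exon_lengths)
    intron_lengths = tuple(int(x) for x in intron_lengths)
    if len(exon_lengths) != len(intron_lengths) + 1:
        raise SpecError("need exactly one more exon than intron")
    if any(x <= 0 for x in exon_lengths + intron_lengths):
        raise SpecError("exon and intron lengths must be positive")
    coding = sum(exon_lengths)
    if coding % 3 != 0:
        raise SpecError(f"total coding length {coding} is not divisible by 3")
    protein_len = coding // 3
    seg = tuple(int(x) for x in segment_lens)
    if len(seg) != 4 or any(x < 0 for x in seg):
        raise SpecError("segment_lens must be (signal, pro, mature, extra) >= 0")
    if sum(seg) != protein_len:
        raise SpecError(
            f"segment lengths sum to {sum(seg)} but exons imply {protein_len} aa"
        )

    rng = np.random.default_rng(seed)
    residues = [AMINO_ACIDS[int(i)] for i in rng.integers(20, size=protein_len)]
    codons = _draw_codons(rng, residues)

    # splice-junction identifiability at each exon boundary
    cut = 0
    for ln in exon_lengths[:-1]:
        cut += ln
        q, o = cut // 3, cut % 3
        allowed = _escape_codons(residues[q], o)
        if not allowed:
            choices = [a for a in AMINO_ACIDS if _escape_codons(a, o)]
            residues[q] = choices[int(rng.integers(len(choices)))]
            allowed = _escape_codons(residues[q], o)
        if codons[q] not in allowed:
            codons[q] = allowed[int(rng.integers(len(allowed)))]

    protein = "".join(residues)
    cds = "".join(codons)
    stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
    utr5 = _rand_nt(rng, utr5_len)
    utr3 = _rand_nt(rng, utr3_len)
    cdna = utr5 + cds + stop + utr3

    intron_seqs = ["GT" + _rand_nt(rng, ln - 4) + "AG" for ln in intron_lengths]
    genomic_parts = [utr5]
    exons = []
    g_cursor = 0
    prev_cut = 0
    cut = 0
    for ln, iseq in zip(exon_lengths[:-1], intron_seqs):
        cut += ln
        piece = cds[prev_cut:cut]
        exon_len = len(piece) + (utr5_len if not exons else 0)
        genomic_parts.append(piece)
        exons.append((g_cursor + 1, g_cursor + exon_len))
        g_cursor += exon_len
        genomic_parts.append(iseq)
        g_cursor += len(iseq)
        prev_cut = cut
    tail = cds[prev_cut:] + stop + utr3
    genomic_parts.append(tail)
    tail_len = len(tail) + (utr5_len if not exons else 0)
    exons.append((g_cursor + 1, g_cursor + tail_len))
    genomic = "".join(genomic_parts)

    model = GeneModel(
        exons=tuple(exons), cds_start_on_cdna=utr5_len + 1, cds_len=coding
    )

    segments = []
    pos = 1
    for role, ln in zip(("signal", "pro", "mature", "trailing"), seg):
        if ln:
            segments.append(Segment(role, pos, pos + ln - 1))
            pos += ln
    annotation = PrecursorAnnotation(segments=tuple(segments))

    bundle = LocusBundle(
        genomic_seq=genomic,
        cdna_seq=cdna,
        protein_seq=protein,
        truth_gene_model=model,
        truth_annotation=annotation,
        seed=seed,
    )
    _check_bundle(bundle)
    return bundle


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------

def diverge_domains(bundle: LocusBundle, subst_rate: float, seed: int) -> LocusBundle:
    """Mutate the HD coding sequence of each repeat independently.

    Substitution-only, nucleotide-level: each HD coding position mutates to a
    different base with probability ``subst_rate``; spacer and cleavage motif
    positions are never touched and truth intervals are unchanged.  A codon
    mutated into a stop codon, or into a basic residue adjacent to another
    basic residue, is reverted: the first would break the bundle's
    translatability invariant, the second would plant a spurious cleavage
    site and break the precursor grammar.  Both reversions slightly lower
    the realized rate at the affected codons.
    """
    if not (0 <= subst_rate < 1):
        raise ValueError("subst_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    model = bundle.truth_gene_model
    cds = list(bundle.cds_seq)
    aa = list(bundle.protein_seq)
    fwd = standard_dna_table.forward_table
    for segment in bundle.truth_annotation.by_role("HD"):
        lo = 3 * (segment.start - 1)  # 0-based on CDS
        hi = 3 * segment.end
        for codon_start in range(lo, hi, 3):
            orig = cds[codon_start : codon_start + 3]
            new = list(orig)
            for k in range(3):
                if rng.random() < subst_rate:
                    base = orig[k]
                    others = [b for b in "ACGT" if b != base]
                    new[k] = others[int(rng.integers(3))]
            q = codon_start // 3
            aa_new = fwd.get("".join(new))
            if aa_new is None:
                new = orig  # stop codon
            elif aa_new in BASIC and (
                (q > 0 and aa[q - 1] in BASIC)
                or (q + 1 < len(aa) and aa[q + 1] in BASIC)
            ):
                new = orig  # would create a spurious dibasic site
            else:
                aa[q] = aa_new
            cds[codon_start : codon_start + 3] = new
    cds = "".join(cds)

    cs = model.cds_start_on_cdna - 1
    cdna = bundle.cdna_seq[:cs] + cds + bundle.cdna_seq[cs + model.cds_len :]
    # rebuild genomic by replacing exonic stretches with the new transcript
    genomic = list(bundle.genomic_seq)
    t = 0
    for (s, e) in model.exons:
        ln = e - s + 1
        genomic[s - 1 : e] = cdna[t : t + ln]
        t += ln
    genomic = "".join(genomic)
    protein = translate(cds).seq
    return LocusBundle(
        genomic_seq=genomic,
        cdna_seq=cdna,
        protein_seq=protein,
        truth_gene_model=model,
        truth_annotation=bundle.truth_annotation,
        seed=seed,
        spec=bundle.spec,
    )


# ---------------------------------------------------------------------------
# random architectures (property-test distribution)
# ---------------------------------------------------------------------------

def random_architecture(rng, max_introns: int = 2) -> ArchitectureSpec:
    """Draw a random valid architecture for round-trip property tests."""
    signal = int(rng.integers(8, 26))
    pro = int(rng.integers(8, 41))
    hld = int(rng.integers(20, 121))
    hd = int(rng.integers(20, 151))
    n_rep = int(rng.integers(0, 11))
    cm = DIBASIC_MOTIFS[int(rng.integers(3))]
    spec = ArchitectureSpec(
        signal_len=signal,
        pro_len=pro,
        hld_len=hld,
        hd_len=hd,
        n_repeats=n_rep,
        cleavage_motif=cm,
        introns=(),
        utr5_len=int(rng.integers(0, 81)),
        utr3_len=int(rng.integers(0, 81)),
        fixed_residues=(),
    )
    n_introns = int(rng.integers(0, max_introns + 1))
    # introns only at free prefix codons, pairwise offsets >= 30 nt apart
    offsets: list[int] = []
    placements = []
    for _ in range(n_introns):
        for _attempt in range(50):
            q = int(rng.integers(1, signal + pro))  # 0-based free codon, not the first
            o = int(rng.integers(3))
            cpos = 3 * q + o
            if cpos < 3 or any(abs(cpos - x) < 30 for x in offsets):
                continue
            offsets.append(cpos)
            length = int(rng.integers(50, 301))
            if o == 0:
                placements.append(IntronPlacement(length=length, after_codon=q))
            else:
                placements.append(
                    IntronPlacement(length=length, within_codon=q + 1, phase=o)
                )
            break
    spec = replace(spec, introns=tuple(placements))
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# gene-family birth-death simulation
# ---------------------------------------------------------------------------

@dataclass
class GeneFamilySim:
    """A simulated gene family with its true event counts."""

    species_tree: dendropy.Tree
    gene_tree: dendropy.Tree
    leaf_to_species: dict[str, str]
    true_duplications: int
    true_losses: int
    rates: tuple[float, float]
    seed: int
    resample_count: int = 0


class _GNode:
    __slots__ = ("children", "species")

    def __init__(self, children=None, species=None):
        self.children = children or []
        self.species = species


def _species_label(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def simulate_gene_family(
    species_tree: dendropy.Tree, dup_rate: float, loss_rate: float, seed: int
) -> GeneFamilySim:
    """Duplication-loss birth-death process along a rooted species tree.

    One gene enters at the root; on every species branch each gene lineage
    duplicates with exponential waiting time at ``dup_rate`` and dies at
    ``loss_rate`` (per unit branch length); surviving lineages follow every
    speciation.  Families that go extinct are resampled with an incremented
    seed, and the number of resamples is reported in ``resample_count``.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    for node in species_tree.preorder_node_iter():
        kids = node.child_nodes()
        if kids and len(kids) != 2:
            raise ValueError("species tree must be binary")
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("species tree must have branch lengths")

    attempt = 0
    while True:
        rng = np.random.default_rng(seed + attempt)
        counts = {"dup": 0, "loss": 0}

        def at_node(snode) -> _GNode | None:
            kids = snode.child_nodes()
            if not kids:
                return _GNode(species=_species_label(snode))
            born = [on_branch(k) for k in kids]
            alive = [g for g in born if g is not None]
            if not alive:
                return None
            if len(alive) == 1:
                return alive[0]
            return _GNode(children=alive)

        def on_branch(snode) -> _GNode | None:
            def sim(t_remaining: float) -> _GNode | None:
                total = dup_rate + loss_rate
                while True:
                    if total <= 0:
                        break
                    wait = rng.exponential(1.0 / total)
                    if wait >= t_remaining:
                        break
                    t_remaining -= wait
                    if rng.random() < (dup_rate / total):
                        counts["dup"] += 1
                        a = sim(t_remaining)
                        b = sim(t_remaining)
                        if a is not None and b is not None:
                            return _GNode(children=[a, b])
                        return a if a is not None else b
                    counts["loss"] += 1
                    return None
                return at_node(snode)

            return sim(float(snode.edge.length))

        root = at_node(species_tree.seed_node)
        if root is not None:
            break
        attempt += 1

    # materialize as a dendropy tree with species_i leaf labels
    per_species: dict[str, int] = {}
    leaf_to_species: dict[str, str] = {}
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(g: _GNode) -> dendropy.Node:
        node = dendropy.Node()
        if not g.children:
            per_species[g.species] = per_species.get(g.species, 0) + 1
            label = f"{g.species}_{per_species[g.species]}"
            node.taxon = taxa.new_taxon(label)
            leaf_to_species[label] = g.species
        else:
            for child in g.children:
                node.add_child(build(child))
        return node

    tree.seed_node = build(root)
    tree.is_rooted = True
    return GeneFamilySim(
        species_tree=species_tree,
        gene_tree=tree,
        leaf_to_species=leaf_to_species,
        true_duplications=counts["dup"],
        true_losses=counts["loss"],
        rates=(dup_rate, loss_rate),
        seed=seed,
        resample_count=attempt,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_bundle(bundle: LocusBundle, outdir, prefix: str = "locus") -> dict:
    """Write a bundle as FASTA (genomic/cDNA/protein), GFF3 and a truth sidecar.

    The GFF3 carries gene/mRNA/exon/CDS features in genomic coordinates plus
    segment child features (signal_peptide, propeptide, mature_peptide,
    spacer, cleavage_site) in cDNA coordinates on the cDNA record, each with
    a Note attribute naming its role.  Returns {name: path}.
    """
    from pathlib import Path

    from .seq_io import GffFeature, NucSeq, ProtSeq, write_fasta, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    gid, cid, pid = f"{prefix}_gene", f"{prefix}_cdna", f"{prefix}_protein"
    for name, rec in (
        ("genomic", NucSeq(gid, bundle.genomic_seq)),
        ("cdna", NucSeq(cid, bundle.cdna_seq)),
        ("protein", ProtSeq(pid, bundle.protein_seq)),
    ):
        path = outdir / f"{prefix}.{name}.fa"
        write_fasta([rec], path)
        paths[name] = path

    model = bundle.truth_gene_model
    feats = [
        GffFeature(gid, "gene", 1, len(bundle.genomic_seq),
                   attributes=(("ID", f"{prefix}.g"),)),
        GffFeature(gid, "mRNA", model.exons[0][0], model.exons[-1][1],
                   attributes=(("ID", f"{prefix}.m"), ("Parent", f"{prefix}.g"))),
    ]
    for i, (s, e) in enumerate(model.exons, 1):
        feats.append(
            GffFeature(gid, "exon", s, e,
                       attributes=(("ID", f"{prefix}.e{i}"),
                                   ("Parent", f"{prefix}.m")))
        )
    # CDS in genomic coordinates (stop codon excluded; see GeneModel)
    cs, ln = model.cds_start_on_cdna, model.cds_len
    t = 0
    for i, (s, e) in enumerate(model.exons, 1):
        exon_len = e - s + 1
        lo = max(cs, t + 1)
        hi = min(cs + ln - 1, t + exon_len)
        if lo <= hi:
            feats.append(
                GffFeature(gid, "CDS", s + (lo - t - 1), s + (hi - t - 1),
                           attributes=(("ID", f"{prefix}.cds"),
                                       ("Parent", f"{prefix}.m")))
            )
        t += exon_len
    role_to_type = {
        "signal": "signal_peptide",
        "pro": "propeptide",
        "HLD": "mature_peptide",
        "HD": "mature_peptide",
        "mature": "mature_peptide",
        "spacer": "spacer",
        "cleavage": "cleavage_site",
        "trailing": "propeptide",
    }
    for seg in bundle.truth_annotation.segments:
        nt_start = cs + 3 * (seg.start - 1)
        nt_end = cs + 3 * seg.end - 1
        feats.append(
            GffFeature(cid, role_to_type[seg.role], nt_start, nt_end,
                       attributes=(("Note", seg.role),))
        )
    gff_path = outdir / f"{prefix}.gff3"
    write_gff3(feats, gff_path)
    paths["gff3"] = gff_path

    sidecar = outdir / f"{prefix}.truth.txt"
    with open(sidecar, "w") as fh:
        fh.write(f"seed\t{bundle.seed}\n")
        fh.write(f"protein_length\t{len(bundle.protein_seq)}\n")
        fh.write(f"cdna_length\t{len(bundle.cdna_seq)}\n")
        fh.write(f"gene_length\t{len(bundle.genomic_seq)}\n")
        fh.write(f"cds_start_on_cdna\t{model.cds_start_on_cdna}\n")
        fh.write(f"cds_len\t{model.cds_len}\n")
        for i, (s, e) in enumerate(model.exons, 1):
            fh.write(f"exon_{i}\t{s}\t{e}\n")
        for i, (s, e) in enumerate(model.introns, 1):
            fh.write(f"intron_{i}\t{s}\t{e}\n")
        for seg in bundle.truth_annotation.segments:
            fh.write(f"segment\t{seg.role}\t{seg.start}\t{seg.end}\n")
    paths["truth"] = sidecar
    return paths
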