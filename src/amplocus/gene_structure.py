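"""Exon/intron structure: cDNA-to-genomic splice mapping and intron arithmetic.

The central operation, :func:`splice_map`, automates the gene/cDNA comparison
used to locate introns: it assumes the cDNA is an exact ordered concatenation
of genomic substrings (same-clone sequencing, no mismatches) and recovers the
unique exon/intron model by greedy left-to-right extension with a
smallest-intron preference at each junction.

Intron phase follows the standard GT-AG convention: the phase is the number
of nucleotides of the interrupted codon already emitted upstream of the
intron (0, 1 or 2).  A phase-0 intron falls cleanly between two codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


class SpliceMapError(ValueError):
    """No consistent exon/intron model; carries the first unmappable offset."""

    def __init__(self, message: str, cdna_offset: int | None = None):
        self.cdna_offset = cdna_offset
        super().__init__(message)


class AmbiguousSpliceError(SpliceMapError):
    """More than one equally small model fits (short-anchor tail ties)."""


@dataclass(frozen=True)
class GeneModel:
    """Exon coordinates on a genomic sequence (+ strand, 1-based inclusive).

    ``cds_len`` excludes the stop codon: the printed exon arithmetic of the
    loci this package models equates CDS length with 3x the protein length,
    and the stop codon sits in the 3' trailing region of the transcript.
    """

    exons: tuple[tuple[int, int], ...]
    cds_start_on_cdna: int = 1
    cds_len: int | None = None
    strand: str = "+"

    def __post_init__(self):
        if self.strand != "+":
            raise ValueError("only + strand models are supported")
        prev_end = 0
        for s, e in self.exons:
            if not (prev_end < s <= e):
                raise ValueError(f"exons not ordered/non-overlapping: {self.exons}")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.introns)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def gene_length(self) -> int:
        return self.exons[-1][1] - self.exons[0][0] + 1

    @property
    def cds_exon_lengths(self) -> tuple[int, ...]:
        """Printed-style CDS exon sizes: transcript exons clipped to the CDS."""
        if self.cds_len is None:
            raise ValueError("model has no CDS annotation")
        cs, ce = self.cds_start_on_cdna, self.cds_start_on_cdna + self.cds_len - 1
        out = []
        t = 0
        for ln in self.exon_lengths:
            lo, hi = t + 1, t + ln
            ov = max(0, min(hi, ce) - max(lo, cs) + 1)
            if ov:
                out.append(ov)
            t += ln
        return tuple(out)

    def spliced(self, genomic: str) -> str:
        return "".join(genomic[s - 1 : e] for s, e in self.exons)


@dataclass(frozen=True)
class IntronReport:
    index: int           # 1-based intron number
    length: int          # nt
    phase: int | str     # 0 | 1 | 2 | "noncoding"
    codon: int | None    # interrupted codon (phase 1/2); upstream codon k (phase 0)
    boundary: str        # human-readable placement
    residue: str | None  # amino acid of the interrupted codon, if protein given


def _seq(x) -> str:
    return x.seq if hasattr(x, "seq") else str(x)


def splice_map(genomic, cdna, min_anchor: int = 20,
               cds_start_on_cdna: int = 1, cds_len: int | None = None) -> GeneModel:
    """Recover the exon/intron model mapping ``cdna`` onto ``genomic``.

    Greedy left-to-right: genomic and cDNA are matched until the first
    mismatch; the downstream genomic is then searched for the smallest gap
    (intron) at which the next ``min_anchor`` cDNA nucleotides resume exactly,
    and matching continues.  Failure to resume raises :class:`SpliceMapError`
    naming the first unmappable cDNA offset; if the remaining cDNA is shorter
    than ``min_anchor`` and more than one minimal resumption fits, the model
    is ambiguous and :class:`AmbiguousSpliceError` is raised.
    """
    g, c = _seq(genomic), _seq(cdna)
    ng, nc = len(g), len(c)
    exons: list[tuple[int, int]] = []
    i = j = 0  # 0-based cursors on genomic / cdna
    while j < nc:
        exon_start = i
        while i < ng and j < nc and g[i] == c[j]:
            i += 1
            j += 1
        if exon_start == i:
            raise SpliceMapError(
                f"cDNA offset {j + 1} cannot be matched on the genomic sequence",
                cdna_offset=j + 1,
            )
        exons.append((exon_start + 1, i))
        if j >= nc:
            break
        # search for the smallest intron with an exact resumption anchor
        anchor_len = min(min_anchor, nc - j)
        anchor = c[j : j + anchor_len]
        hits = []
        d = 1
        while i + d + anchor_len <= ng:
            if g[i + d : i + d + anchor_len] == anchor:
                hits.append(d)
                if anchor_len == min_anchor:
                    break  # full-length anchor: smallest intron wins outright
            d += 1
        if not hits:
            raise SpliceMapError(
                f"no splice resumption found for cDNA offset {j + 1}",
                cdna_offset=j + 1,
            )
        if len(hits) > 1:
            raise AmbiguousSpliceError(
                f"ambiguous splice: {len(hits)} equally valid resumptions for the "
                f"{anchor_len}-nt tail anchor at cDNA offset {j + 1}",
                cdna_offset=j + 1,
            )
        i += hits[0]
    if i != ng:
        raise SpliceMapError(
            f"{ng - i} genomic nucleotides remain unmatched after the last exon"
        )
    return GeneModel(
        exons=tuple(exons),
        cds_start_on_cdna=cds_start_on_cdna,
        cds_len=cds_len,
    )


def intron_report(model: GeneModel, protein: str | None = None) -> list[IntronReport]:
    """Phase and interrupted codon of every intron in ``model``.

    Phase = (coding nucleotides upstream of the intron) mod 3.  Phase 1/2
    introns interrupt codon floor(upstream/3)+1; phase 0 introns fall between
    codons upstream/3 and upstream/3 + 1.  Introns upstream of the CDS are
    reported with phase "noncoding".
    """
    if model.cds_len is None:
        raise ValueError("intron_report requires a model with CDS annotation")
    if protein is not None:
        protein = _seq(protein)
    reports = []
    cum = 0
    for idx, ((s, e), exon_len) in enumerate(
        zip(model.introns, model.exon_lengths), start=1
    ):
        cum += model.exon_lengths[idx - 1]
        upstream = cum - (model.cds_start_on_cdna - 1)
        length = e - s + 1
        if upstream <= 0 or upstream >= model.cds_len:
            reports.append(
                IntronReport(idx, length, "noncoding", None, "outside the CDS", None)
            )
            continue
        phase = upstream % 3
        if phase == 0:
            k = upstream // 3
            codon, boundary = k, f"between codons {k}|{k + 1}"
            residue = protein[k - 1] if protein else None
        else:
            codon = upstream // 3 + 1
            boundary = f"within codon {codon}"
            residue = protein[codon - 1] if protein else None
        reports.append(IntronReport(idx, length, phase, codon, boundary, residue))
    return reports


def coding_protein_length(model_or_lengths) -> int:
    """Protein length implied by CDS exon sizes: sum / 3 (error if indivisible)."""
    if isinstance(model_or_lengths, GeneModel):
        lengths: Sequence[int] = model_or_lengths.cds_exon_lengths
    else:
        lengths = tuple(model_or_lengths)
    total = sum(lengths)
    if total % 3 != 0:
        raise ValueError(f"total CDS length {total} is not divisible by 3")
    return total // 3
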