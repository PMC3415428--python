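"""Readers and writers for the standard formats the pipeline touches.

FASTA parsing is delegated to Biopython, Newick handling to dendropy; this
module adds the thin, strict layer the rest of the package relies on:
alphabet enforcement on load, named parse errors that carry a line number,
deterministic writing, and standard-code codon translation.

Coordinates everywhere in this package are 1-based and inclusive, matching
the residue numbering used for gene-structure reports (e.g. "codon 39");
GFF3 uses the same convention, so no conversion happens at that boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

NUC_ALPHABET = frozenset("ACGTN")
PROT_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

STOP_CODONS = ("TAA", "TAG", "TGA")


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TranslationError(ValueError):
    """CDS not translatable under the standard genetic code rules used here."""


@dataclass(frozen=True)
class NucSeq:
    """A named nucleotide sequence over the alphabet ACGTN."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - NUC_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProtSeq:
    """A named protein sequence over the 20 standard amino acids plus X."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - PROT_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _find_bad_line(path_or_text, predicate) -> int | None:
    """Locate the first line satisfying ``predicate`` (for error reporting)."""
    if isinstance(path_or_text, (str, Path)) and Path(str(path_or_text)).exists():
        lines = Path(path_or_text).read_text().splitlines()
    else:
        lines = str(path_or_text).splitlines()
    for lineno, line in enumerate(lines, start=1):
        if predicate(line):
            return lineno
    return None


def read_fasta(path, kind: str = "nucleotide") -> list:
    """Read a FASTA file into an ordered list of ``NucSeq`` or ``ProtSeq``.

    Lowercase residues are uppercased (and flagged in the log); empty records
    and illegal characters raise :class:`FastaParseError` with a line number.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError(f"kind must be 'nucleotide' or 'protein', got {kind!r}")
    alphabet = NUC_ALPHABET if kind == "nucleotide" else PROT_ALPHABET
    cls = NucSeq if kind == "nucleotide" else ProtSeq

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        raw = str(rec.seq)
        if not raw:
            line = _find_bad_line(path, lambda l, h=rec.id: l.startswith(">") and h in l)
            raise FastaParseError(f"empty record {rec.id!r}", line=line)
        if raw != raw.upper():
            log.warning("record %r: lowercase residues uppercased on load", rec.id)
            raw = raw.upper()
        bad = set(raw) - alphabet
        if bad:
            ch = sorted(bad)[0]
            line = _find_bad_line(
                path, lambda l: not l.startswith(">") and ch in l.upper()
            )
            raise FastaParseError(
                f"record {rec.id!r}: illegal character {ch!r} for {kind} sequence",
                line=line,
            )
        out.append(cls(id=rec.id, seq=raw))
    return out


def write_fasta(seqs: Iterable, path, width: int = 60) -> None:
    """Write records with lines wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


def translate(cds, allow_internal_stop: bool = False) -> ProtSeq:
    """Translate a CDS under the standard genetic code.

    The input length must be divisible by 3.  A single trailing stop codon is
    tolerated and dropped; an internal stop raises :class:`TranslationError`
    naming the 1-based codon index unless ``allow_internal_stop`` is set
    (internal stops then appear as ``*``-free ``X``).
    """
    ident, seq = (cds.id, cds.seq) if isinstance(cds, NucSeq) else ("cds", str(cds))
    if len(seq) % 3 != 0:
        raise TranslationError(
            f"CDS length {len(seq)} is not divisible by 3 for {ident!r}"
        )
    prot = str(Seq(seq).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        idx = prot.index("*") + 1
        if not allow_internal_stop:
            raise TranslationError(f"internal stop codon at codon {idx} in {ident!r}")
        prot = prot.replace("*", "X")
    if not prot:
        raise TranslationError(f"CDS {ident!r} translates to an empty protein")
    return ProtSeq(id=ident, seq=prot)


# -- Newick ------------------------------------------------------------------

def parse_newick(text: str, taxon_namespace=None) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree.

    Internal node labels are preserved as plain labels (this is where integer
    bootstrap supports travel); malformed input raises NewickParseError.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"cannot parse Newick: {exc}") from exc
    return tree


def read_newick(path, taxon_namespace=None) -> dendropy.Tree:
    return parse_newick(Path(path).read_text(), taxon_namespace=taxon_namespace)


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(tree_to_newick(tree))


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def node_support(node) -> float | None:
    """Bootstrap support of an internal node (attribute or numeric label)."""
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


# -- GFF3 --------------------------------------------------------------------

@dataclass(frozen=True)
class GffFeature:
    seqid: str
    ftype: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    source: str = "amplocus"
    score: str = "."
    strand: str = "+"
    phase: str = "."
    attributes: tuple = field(default_factory=tuple)  # ((key, value), ...)

    def line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes) or "."
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.ftype,
                str(self.start),
                str(self.end),
                self.score,
                self.strand,
                self.phase,
                attrs,
            ]
        )


def write_gff3(features: Sequence[GffFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(f.line() + "\n")
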