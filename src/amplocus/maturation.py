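"""In-silico three-step proteolytic maturation of a multipeptide precursor.

The model follows the yeast alpha-mating-factor-style maturation cascade:

1. a KEX2-like endoprotease cuts C-terminal to each dibasic site (RR/KR/RK);
2. a KEX1-like carboxypeptidase removes the two basic residues from each
   fragment's C-terminus;
3. a dipeptidyl aminopeptidase removes N-terminal E/D-A/P dipeptides,
   peeling the EAEP spacer off each repeat (EA, then EP).

Applied after signal-peptide removal, and with the pro-derived fragment
discarded, this releases the hymenoptaecin-like peptide followed by the
repeated hymenoptaecin peptides.  The default dipeptide set {EA, EP, DA, DP}
covers the E/D-A/P rule; spacer variants such as EANP require widening the
set (``dipeptides`` argument) because AN is not an E/D-A/P dipeptide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .annotations import CleavageSite, MaturePeptide
from .precursor import scan_cleavage_sites, segment_precursor
from .synthetic import ArchitectureSpec

log = logging.getLogger(__name__)

DEFAULT_DIPEPTIDES = frozenset({"EA", "EP", "DA", "DP"})


@dataclass(frozen=True)
class Fragment:
    sequence: str
    start: int  # 1-based on the parent protein
    end: int

    def __len__(self) -> int:
        return len(self.sequence)


def _seq(x) -> str:
    return x.seq if hasattr(x, "seq") else str(x)


def endoprotease_cut(protein, sites: list[CleavageSite]) -> list[Fragment]:
    """Split immediately after each site's last residue; order preserved.

    Empty fragments (e.g. a trailing cut at the very end) are dropped and
    logged; the concatenation of the returned fragments restores the protein.
    """
    s = _seq(protein)
    cuts = sorted(site.position for site in sites)
    fragments: list[Fragment] = []
    prev = 0
    for cut in cuts + [len(s)]:
        if cut == prev:
            if cut < len(s) or not cuts:
                log.debug("dropping empty fragment at position %d", prev + 1)
            continue
        fragments.append(Fragment(s[prev:cut], prev + 1, cut))
        prev = cut
    if not fragments:
        fragments = [Fragment(s, 1, len(s))]
    return fragments


def carboxypeptidase_trim(fragment: str, max_trim: int = 2) -> str:
    """Strip C-terminal R/K residues, at most ``max_trim`` (both basics).

    ``max_trim=None`` trims an unlimited trailing basic run.
    """
    s = str(fragment)
    trimmed = 0
    while s and s[-1] in "RK" and (max_trim is None or trimmed < max_trim):
        s = s[:-1]
        trimmed += 1
    return s


def dipeptidyl_trim(fragment: str, dipeptides=DEFAULT_DIPEPTIDES) -> str:
    """Iteratively remove N-terminal dipeptides from ``dipeptides``."""
    s = str(fragment)
    while len(s) >= 2 and s[:2] in dipeptides:
        s = s[2:]
    return s


def mature_peptides(
    protein,
    spec: ArchitectureSpec,
    dipeptides=DEFAULT_DIPEPTIDES,
    max_basic_trim: int = 2,
) -> list[MaturePeptide]:
    """Run the full three-step maturation and return the released peptides.

    The precursor must parse under ``spec`` (parse errors propagate).  The
    first returned peptide derives from the HLD, the rest from the HDs, each
    carrying its provenance interval on the precursor.
    """
    peptides, _ = _run_maturation(protein, spec, dipeptides, max_basic_trim)
    return peptides


def maturation_accounting(
    protein,
    spec: ArchitectureSpec,
    dipeptides=DEFAULT_DIPEPTIDES,
    max_basic_trim: int = 2,
) -> dict:
    """Exact residue accounting for one maturation run (mass conservation)."""
    _, accounting = _run_maturation(protein, spec, dipeptides, max_basic_trim)
    return accounting


def _run_maturation(protein, spec, dipeptides, max_basic_trim):
    s = _seq(protein)
    segment_precursor(s, spec)  # validates the grammar; errors propagate

    sites = scan_cleavage_sites(s)
    fragments = endoprotease_cut(s, sites)
    # the first fragment carries signal+pro (+ its cleavage motif): discarded.
    # NOTE the grammar's pro+cleavage convention is an assumption — whether the
    # pro fragment carries its own dibasic pair is not observable from cDNA.
    discarded = fragments[0]
    peptides: list[MaturePeptide] = []
    basic_removed = 0
    spacer_removed = 0
    for idx, frag in enumerate(fragments[1:]):
        seq = frag.sequence
        after_cpase = carboxypeptidase_trim(seq, max_trim=max_basic_trim)
        basic_removed += len(seq) - len(after_cpase)
        after_dpap = dipeptidyl_trim(after_cpase, dipeptides=dipeptides)
        spacer_removed += len(after_cpase) - len(after_dpap)
        if not after_dpap:
            log.warning("fragment %d fully consumed by trimming", idx + 2)
            continue
        n_trim_front = len(after_cpase) - len(after_dpap)
        start = frag.start + n_trim_front
        end = frag.end - (len(seq) - len(after_cpase))
        role = "HLD" if idx == 0 else "HD"
        peptides.append(
            MaturePeptide(sequence=after_dpap, source_interval=(start, end), role=role)
        )
    accounting = {
        "total_residues": len(s),
        "signal_pro_discarded": len(discarded),
        "basic_residues_trimmed": basic_removed,
        "spacer_residues_trimmed": spacer_removed,
        "peptide_residues": sum(len(p) for p in peptides),
    }
    assert (
        accounting["signal_pro_discarded"]
        + accounting["basic_residues_trimmed"]
        + accounting["spacer_residues_trimmed"]
        + accounting["peptide_residues"]
        == accounting["total_residues"]
    ), "maturation accounting does not balance"
    return peptides, accounting
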