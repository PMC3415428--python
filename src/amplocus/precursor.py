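"""Rule-based segmentation of a multipeptide precursor protein.

The parser is the left inverse of the synthetic generator: given an
:class:`~amplocus.synthetic.ArchitectureSpec` template it consumes the
signal and pro segments by length, then recognizes the cleavage-motif /
spacer grammar to delimit the hymenoptaecin-like domain (HLD) and every
repeated hymenoptaecin domain (HD).  Signal/pro boundaries come from the
template, not from a signal-peptide predictor: the package is deliberately
self-contained and the boundary lengths are part of the architecture.

Dibasic site recognition is a plain left-to-right greedy scan (a residue
belongs to at most one site; in a run like RRR the leftmost pair wins),
standing in for neural-network convertase-site prediction.  RXXR sites,
which occur in some other species' precursors, are off by default.
"""

from __future__ import annotations

import logging
from typing import Iterable

from .annotations import CleavageSite, PrecursorAnnotation, Segment
from .synthetic import ArchitectureSpec, DIBASIC_MOTIFS

log = logging.getLogger(__name__)


class PrecursorParseError(ValueError):
    """The grammar required a motif that is not present."""

    def __init__(self, message: str, position: int | None = None,
                 expected: str | None = None):
        self.position = position
        self.expected = expected
        super().__init__(message)


def _seq(x) -> str:
    return x.seq if hasattr(x, "seq") else str(x)


def scan_cleavage_sites(
    protein,
    motifs: Iterable[str] = DIBASIC_MOTIFS,
    include_rxxr: bool = False,
) -> list[CleavageSite]:
    """All non-overlapping convertase sites, left-to-right greedy."""
    s = _seq(protein)
    if not s:
        raise ValueError("empty protein")
    motifs = tuple(motifs)
    sites: list[CleavageSite] = []
    i = 0
    n = len(s)
    while i < n - 1:
        pair = s[i : i + 2]
        if pair in motifs:
            sites.append(CleavageSite(position=i + 2, motif=pair))
            i += 2
            continue
        if include_rxxr and i + 4 <= n and s[i] == "R" and s[i + 3] == "R":
            sites.append(CleavageSite(position=i + 4, motif=s[i : i + 4]))
            i += 4
            continue
        i += 1
    return sites


def _next_dibasic(s: str, start0: int, motifs: tuple[str, ...]) -> int | None:
    """0-based start of the first dibasic pair at or after ``start0``."""
    for i in range(start0, len(s) - 1):
        if s[i : i + 2] in motifs:
            return i
    return None


def segment_precursor(protein, spec: ArchitectureSpec) -> PrecursorAnnotation:
    """Deterministic grammar parse of a precursor against its template.

    Consumes signal_len, pro_len, a cleavage motif, the HLD up to the next
    cleavage motif, then (spacer, HD up to next cleavage motif) repeatedly
    until the protein is exhausted.  HD length uniformity and first-residue
    expectations are validated but reported as warnings, not errors — real
    precursor clones show substantial sequence variability.
    """
    s = _seq(protein)
    motifs = tuple(m for m in DIBASIC_MOTIFS if len(m) == len(spec.cleavage_motif))
    cm_len = len(spec.cleavage_motif)
    sp = spec.spacer_motif
    warnings: list[str] = []
    segments: list[Segment] = []
    pos = 0  # 0-based cursor

    def need(n_res: int, what: str):
        if pos + n_res > len(s):
            raise PrecursorParseError(
                f"protein ends before the expected {what}",
                position=pos + 1,
                expected=what,
            )

    need(spec.signal_len + spec.pro_len + cm_len, "signal+pro+cleavage")
    segments.append(Segment("signal", 1, spec.signal_len))
    pos = spec.signal_len
    segments.append(Segment("pro", pos + 1, pos + spec.pro_len))
    pos += spec.pro_len

    def expect_cleavage():
        nonlocal pos
        window = s[pos : pos + cm_len]
        if window not in motifs:
            raise PrecursorParseError(
                f"expected cleavage motif at residue {pos + 1}, found {window!r}",
                position=pos + 1,
                expected="/".join(motifs),
            )
        segments.append(Segment("cleavage", pos + 1, pos + cm_len))
        pos += cm_len

    expect_cleavage()

    # HLD runs to the next dibasic site
    hld_start = pos
    nxt = _next_dibasic(s, pos, motifs)
    if nxt is None or nxt == pos:
        raise PrecursorParseError(
            f"no cleavage motif terminating the HLD after residue {pos + 1}",
            position=pos + 1,
            expected="/".join(motifs),
        )
    segments.append(Segment("HLD", hld_start + 1, nxt))
    if s[hld_start] != spec.hld_first_residue:
        warnings.append(
            f"HLD starts with {s[hld_start]!r}, expected {spec.hld_first_residue!r}"
        )
    if nxt - hld_start != spec.hld_len:
        warnings.append(f"HLD length {nxt - hld_start}, expected {spec.hld_len}")
    pos = nxt
    expect_cleavage()

    hd_lengths: list[int] = []
    n_hd = 0
    while pos < len(s):
        window = s[pos : pos + len(sp)]
        if window != sp:
            if pos == len(s):
                break
            raise PrecursorParseError(
                f"expected spacer motif {sp!r} at residue {pos + 1}, found {window!r}",
                position=pos + 1,
                expected=sp,
            )
        segments.append(Segment("spacer", pos + 1, pos + len(sp)))
        pos += len(sp)
        hd_start = pos
        nxt = _next_dibasic(s, pos, motifs)
        if nxt is None or nxt == pos:
            raise PrecursorParseError(
                f"no cleavage motif terminating the HD after residue {pos + 1}",
                position=pos + 1,
                expected="/".join(motifs),
            )
        segments.append(Segment("HD", hd_start + 1, nxt))
        n_hd += 1
        hd_lengths.append(nxt - hd_start)
        if s[hd_start] != spec.hd_first_residue:
            warnings.append(
                f"HD {n_hd} starts with {s[hd_start]!r}, "
                f"expected {spec.hd_first_residue!r}"
            )
        pos = nxt
        expect_cleavage()

    if len(set(hd_lengths)) > 1:
        warnings.append(f"HD lengths are not uniform: {hd_lengths}")
    elif hd_lengths and hd_lengths[0] != spec.hd_len:
        warnings.append(f"HD length {hd_lengths[0]}, expected {spec.hd_len}")
    for w in warnings:
        log.warning("precursor parse: %s", w)
    return PrecursorAnnotation(segments=tuple(segments), warnings=tuple(warnings))


def map_segments_to_cdna(
    annotation: PrecursorAnnotation, cds_start_on_cdna: int
) -> list[tuple[Segment, tuple[int, int]]]:
    """cDNA nucleotide interval of each segment (1-based inclusive).

    Residue i maps to nt [cds_start + 3(i-1), cds_start + 3i - 1].
    """
    if cds_start_on_cdna < 1:
        raise ValueError("cds_start_on_cdna must be >= 1")
    out = []
    for seg in annotation.segments:
        nt_start = cds_start_on_cdna + 3 * (seg.start - 1)
        nt_end = cds_start_on_cdna + 3 * seg.end - 1
        out.append((seg, (nt_start, nt_end)))
    return out
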