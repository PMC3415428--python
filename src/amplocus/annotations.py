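"""Shared annotation records: residue segments, cleavage sites, mature peptides.

These are the role-labelled intervals exchanged between the synthetic-locus
generator (which emits them as ground truth), the precursor parser (which
reconstructs them from sequence alone) and the maturation simulator.
All intervals are 1-based inclusive residue coordinates on the precursor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: segment roles the grammar knows about
ROLES = ("signal", "pro", "cleavage", "HLD", "spacer", "HD", "mature", "trailing")


@dataclass(frozen=True)
class Segment:
    role: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown segment role {self.role!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad segment interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def extract(self, protein: str) -> str:
        return protein[self.start - 1 : self.end]


@dataclass(frozen=True)
class PrecursorAnnotation:
    """Ordered role-labelled segments tiling a precursor protein."""

    segments: tuple[Segment, ...]
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        pos = 1
        for seg in self.segments:
            if seg.start != pos:
                raise ValueError(
                    f"segments do not tile: expected start {pos}, got {seg.start} "
                    f"({seg.role})"
                )
            pos = seg.end + 1

    @property
    def n_hd(self) -> int:
        return sum(1 for s in self.segments if s.role == "HD")

    @property
    def protein_length(self) -> int:
        return self.segments[-1].end if self.segments else 0

    def by_role(self, role: str) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.role == role)


@dataclass(frozen=True)
class CleavageSite:
    """A dibasic (or RXXR) proprotein-convertase site.

    ``position`` is the 1-based index of the LAST residue of the motif; the
    scissile bond is C-terminal to that residue.
    """

    position: int
    motif: str

    @property
    def start(self) -> int:
        return self.position - len(self.motif) + 1

    def matches(self, protein: str) -> bool:
        window = protein[self.start - 1 : self.position]
        if len(self.motif) == 2:
            return window == self.motif
        # RXXR: only the flanking arginines are literal
        return len(window) == 4 and window[0] == "R" and window[3] == "R"


@dataclass(frozen=True)
class MaturePeptide:
    """A peptide released by in-silico maturation.

    ``source_interval`` points back at the residues of the precursor that
    survive trimming.  A glutamine N-terminus marks the peptide as capable of
    pyroglutamate formation (N-terminal blocking by cyclization).
    """

    sequence: str
    source_interval: tuple[int, int]
    role: str = "HD"

    @property
    def n_term(self) -> str:
        return self.sequence[0]

    @property
    def pyroglutamate_capable(self) -> bool:
        return self.n_term == "Q"

    def __len__(self) -> int:
        return len(self.sequence)
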