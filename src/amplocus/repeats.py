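"""De-novo tandem repeat detection in nucleotide sequences.

Detection mirrors how a long in-frame repeat reveals itself during cDNA
cloning: the sequence matches itself at an offset equal to the repeat
period.  The detector seeds candidate periods with exact k-mer self-matches
(k = 12) at offsets within [min_period, max_period], extends each candidate
to a maximal ungapped array by copy-versus-consensus comparison, and
resolves overlapping reports by highest copies x period, then smallest
period.  The copy model is ungapped (substitutions only, no indels), which
matches exact-length biological repeat units.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass


@dataclass(frozen=True)
class RepeatAnnotation:
    period: int
    copies: float          # fractional: includes partial edge copies
    full_copies: int
    start: int             # 1-based inclusive span on the input
    end: int
    consensus: str
    mean_identity: float   # over full copies vs consensus

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _seq(x) -> str:
    return x.seq if hasattr(x, "seq") else str(x)


def _consensus(copies: list[str]) -> str:
    """Per-column majority vote, ties broken alphabetically."""
    out = []
    for col in zip(*copies):
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
        out.append(best[0])
    return "".join(out)


def _identity(a: str, b: str) -> float:
    if not a or len(a) != len(b):
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def find_tandem_repeats(
    seq,
    min_period: int = 30,
    max_period: int = 600,
    min_copies: int = 2,
    min_identity: float = 0.8,
    k: int = 12,
    max_candidates: int = 40,
) -> list[RepeatAnnotation]:
    """Detect tandem repeat arrays; empty result when nothing qualifies.

    Returns annotations ranked best-first (copies x period descending, then
    smallest period, then leftmost start); overlapping lower-ranked arrays
    are suppressed.
    """
    s = _seq(seq)
    n = len(s)
    if n <= 2 * min_period:
        raise ValueError(
            f"sequence of length {n} too short for min_period {min_period}"
        )

    # k-mer self-match seeding
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        positions[s[i : i + k]].append(i)
    support: dict[int, list[int]] = defaultdict(list)
    for pos_list in positions.values():
        if len(pos_list) < 2:
            continue
        for a_idx in range(len(pos_list) - 1):
            for b_idx in range(a_idx + 1, len(pos_list)):
                d = pos_list[b_idx] - pos_list[a_idx]
                if min_period <= d <= max_period:
                    support[d].append(pos_list[a_idx])

    candidates = sorted(
        support.items(), key=lambda kv: (-len(kv[1]), kv[0])
    )[:max_candidates]

    arrays: list[RepeatAnnotation] = []
    for period, seeds in candidates:
        arrays.extend(
            _extend_candidate(s, period, sorted(set(seeds)), min_copies,
                              min_identity, k)
        )

    arrays.sort(key=lambda r: (-(r.full_copies * r.period), r.period, r.start))
    kept: list[RepeatAnnotation] = []
    for arr in arrays:
        if any(not (arr.end < kept_arr.start or arr.start > kept_arr.end)
               for kept_arr in kept):
            continue
        kept.append(arr)
    return kept


def _extend_candidate(s, period, seeds, min_copies, min_identity, k):
    """Grow each seed cluster into a maximal array; may yield several arrays."""
    n = len(s)
    out = []
    # cluster seeds whose self-match diagonals are within one period
    clusters: list[list[int]] = []
    for pos in seeds:
        if clusters and pos - clusters[-1][-1] <= period:
            clusters[-1].append(pos)
        else:
            clusters.append([pos])
    for cluster in clusters:
        lo = cluster[0]
        hi = cluster[-1] + k + period  # the matched partner extends the span
        hi = min(hi, n)
        m = (hi - lo) // period
        if m < min_copies:
            continue
        copies = [s[lo + j * period : lo + (j + 1) * period] for j in range(m)]
        cons = _consensus(copies)
        # extend outward by whole copies against the fixed consensus
        start = lo
        while start - period >= 0 and _identity(
            s[start - period : start], cons
        ) >= min_identity:
            start -= period
            copies.insert(0, s[start : start + period])
        end = lo + m * period
        while end + period <= n and _identity(
            s[end : end + period], cons
        ) >= min_identity:
            copies.append(s[end : end + period])
            end += period
        cons = _consensus(copies)
        idents = [_identity(c, cons) for c in copies]
        mean_ident = sum(idents) / len(idents)
        if mean_ident < min_identity or len(copies) < min_copies:
            continue
        # partial copies at the edges (a leading/trailing fraction of the unit)
        lead = 0
        for t in range(period - 1, 0, -1):
            if start - t >= 0 and _identity(s[start - t : start], cons[-t:]) >= min_identity:
                lead = t
                break
        trail = 0
        for t in range(period - 1, 0, -1):
            if end + t <= n and _identity(s[end : end + t], cons[:t]) >= min_identity:
                trail = t
                break
        out.append(
            RepeatAnnotation(
                period=period,
                copies=(len(copies) * period + lead + trail) / period,
                full_copies=len(copies),
                start=start - lead + 1,
                end=end + trail,
                consensus=cons,
                mean_identity=mean_ident,
            )
        )
    return out


def amplicon_ladder(full_length: int, period: int, copies: int) -> list[int]:
    """Predicted PCR-artifact ladder lengths: {full_length - i*period, i=0..copies}.

    Models amplification slippage across a tandem array: products missing
    1..copies repeat units accompany the full-length product.
    """
    if full_length <= 0 or period <= 0 or copies < 0:
        raise ValueError("full_length and period must be positive, copies >= 0")
    return [full_length - i * period for i in range(copies + 1)]
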