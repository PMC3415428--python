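"""Distance phylogenetics for cleavage-site domain fragments.

The chain implemented here — global affine-gap alignment, progressive MSA on
a distance guide order, conserved-block cleaning, p/Poisson distances,
NJ/BioNJ agglomeration, column-bootstrap supports and low-support collapse —
is a distance-method stand-in for the usual translator/Gblocks/ML pipeline.
The claims it supports are topological (which domains form clades), not
likelihood-based.

Determinism contracts, all of which tests rely on:

* DP traceback prefers diagonal, then up (consuming the first profile), then
  left;
* NJ/BioNJ Q-criterion ties break on the lexicographically smallest pair of
  cluster keys (a cluster key is the sorted tuple of its leaf labels);
* negative branch lengths are clamped to zero with the deficit moved to the
  sister branch;
* BioNJ uses the standard one-parameter variance-weighted reduction: the
  weight lambda minimizes the variance of the new distance estimates, with
  initial variances equal to the distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log as _ln

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

GAP = "-"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class AlignmentError(ValueError):
    pass


class SaturatedDistanceError(ValueError):
    pass


class BlockCleaningError(ValueError):
    pass


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows keyed by identifier."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    kind: str  # "protein" | "nucleotide"

    def __post_init__(self):
        if len(self.ids) != len(self.rows) or not self.rows:
            raise AlignmentError("ids and rows must be parallel and non-empty")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise AlignmentError("rows have unequal lengths")
        for j in range(width):
            if all(r[j] == GAP for r in self.rows):
                raise AlignmentError(f"column {j + 1} is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _subst(kind: str):
    if kind == "protein":
        mat = _BLOSUM62

        def score(a: str, b: str) -> float:
            return float(mat[a, b])

    else:

        def score(a: str, b: str) -> float:
            return 1.0 if a == b else -1.0

    return score


def _guess_kind(seqs) -> str:
    chars = set()
    for s in seqs:
        chars |= set(_str(s))
    return "nucleotide" if chars <= set("ACGTN-") else "protein"


def _str(x) -> str:
    return x.seq if hasattr(x, "seq") else str(x)


def _id(x, fallback: str) -> str:
    return x.id if hasattr(x, "id") else fallback


# ---------------------------------------------------------------------------
# affine-gap profile alignment (Gotoh)
# ---------------------------------------------------------------------------

def _profile_columns(rows: tuple[str, ...]):
    """Per-column non-gap residue counts."""
    cols = []
    for j in range(len(rows[0])):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[j]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        cols.append(counts)
    return cols


def _align_profiles(rows_a, rows_b, kind, gap_open, gap_extend):
    """Global affine alignment of two profiles; returns (rows_a', rows_b', score).

    Column-column substitution score is the average pairwise residue score
    (gap characters inside a profile contribute zero and dilute the average);
    a gap run of length L costs gap_open + gap_extend * L, charged once per
    profile regardless of row count.
    """
    score = _subst(kind)
    cols_a = _profile_columns(rows_a)
    cols_b = _profile_columns(rows_b)
    na, nb = len(cols_a), len(cols_b)
    wa, wb = len(rows_a), len(rows_b)

    def colscore(i, j):
        tot = 0.0
        for a, ca in cols_a[i].items():
            for b, cb in cols_b[j].items():
                tot += ca * cb * score(a, b)
        return tot / (wa * wb)

    NEG = float("-inf")
    open_cost = gap_open + gap_extend
    M = [[NEG] * (nb + 1) for _ in range(na + 1)]
    X = [[NEG] * (nb + 1) for _ in range(na + 1)]  # gap in B (consume A)
    Y = [[NEG] * (nb + 1) for _ in range(na + 1)]  # gap in A (consume B)
    M[0][0] = 0.0
    for i in range(1, na + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, nb + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + colscore(i - 1, j - 1)
            X[i][j] = max(
                max(M[i - 1][j], Y[i - 1][j]) - open_cost,
                X[i - 1][j] - gap_extend,
            )
            Y[i][j] = max(
                max(M[i][j - 1], X[i][j - 1]) - open_cost,
                Y[i][j - 1] - gap_extend,
            )
        X[i][0] = -(gap_open + gap_extend * i)
    final = max(M[na][nb], X[na][nb], Y[na][nb])

    # traceback, preferring diagonal, then up, then left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = na, nb
    if M[i][j] == final:
        state = "M"
    elif X[i][j] == final:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            out_a.append("A")
            out_b.append("B")
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if M[i][j] == prev:
                state = "M"
            elif X[i][j] == prev:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            val = X[i][j]
            out_a.append("A")
            out_b.append("-")
            came_open = max(M[i - 1][j], Y[i - 1][j]) - open_cost
            i -= 1
            if abs(val - came_open) < 1e-9:
                state = "M" if M[i][j] >= Y[i][j] else "Y"
            else:
                state = "X"
        else:
            val = Y[i][j]
            out_a.append("-")
            out_b.append("B")
            came_open = max(M[i][j - 1], X[i][j - 1]) - open_cost
            j -= 1
            if abs(val - came_open) < 1e-9:
                state = "M" if M[i][j] >= X[i][j] else "X"
            else:
                state = "Y"
    ops = list(reversed(out_a)), list(reversed(out_b))

    new_a = ["" for _ in rows_a]
    new_b = ["" for _ in rows_b]
    ia = ib = 0
    for opa, opb in zip(*ops):
        if opa == "A":
            for r, row in enumerate(rows_a):
                new_a[r] += row[ia]
            ia += 1
        else:
            for r in range(len(rows_a)):
                new_a[r] += GAP
        if opb == "B":
            for r, row in enumerate(rows_b):
                new_b[r] += row[ib]
            ib += 1
        else:
            for r in range(len(rows_b)):
                new_b[r] += GAP
    return tuple(new_a), tuple(new_b), final


def pairwise_align(a, b, kind: str | None = None,
                   gap_open: float = 10.0, gap_extend: float = 0.5):
    """Optimal global affine-gap alignment of two sequences.

    Protein scoring uses BLOSUM62; nucleotide scoring is match +1 /
    mismatch -1.  Returns ``(Alignment, score)``.
    """
    sa, sb = _str(a), _str(b)
    if kind is None:
        kind = _guess_kind([sa, sb])
    ra, rb, score = _align_profiles((sa,), (sb,), kind, gap_open, gap_extend)
    ids = (_id(a, "seq1"), _id(b, "seq2"))
    return Alignment(ids=ids, rows=(ra[0], rb[0]), kind=kind), score


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def _kmer_distance(s1: str, s2: str, k: int) -> float:
    if len(s1) < k or len(s2) < k:
        k = 1
    k1 = {s1[i : i + k] for i in range(len(s1) - k + 1)}
    k2 = {s2[i : i + k] for i in range(len(s2) - k + 1)}
    union = k1 | k2
    if not union:
        return 0.0
    return 1.0 - len(k1 & k2) / len(union)


def progressive_msa(seqs, kind: str | None = None,
                    gap_open: float = 10.0, gap_extend: float = 0.5) -> Alignment:
    """Progressive multiple alignment on an NJ guide order.

    Guide distances are k-mer set distances (k = 3 for protein, 5 for
    nucleotide); profiles are merged pairwise in NJ agglomeration order with
    the same affine profile-profile aligner used for pairwise alignment.
    Deterministic and invariant to input order (rows are returned in input
    order; the column set does not depend on it).
    """
    seq_list = [( _id(s, f"seq{i+1}"), _str(s)) for i, s in enumerate(seqs)]
    if len(seq_list) < 2:
        raise AlignmentError("progressive_msa needs at least 2 sequences")
    if len({sid for sid, _ in seq_list}) != len(seq_list):
        raise AlignmentError("duplicate sequence identifiers")
    if kind is None:
        kind = _guess_kind([s for _, s in seq_list])
    k = 5 if kind == "nucleotide" else 3

    # clusters keyed by sorted leaf-label tuples; NJ-style agglomeration order
    clusters: dict[tuple, tuple[tuple[str, ...], tuple[str, ...]]] = {
        (sid,): ((sid,), (s,)) for sid, s in seq_list
    }
    dist: dict[frozenset, float] = {}
    keys = sorted(clusters)
    for x in range(len(keys)):
        for y in range(x + 1, len(keys)):
            dist[frozenset((keys[x], keys[y]))] = _kmer_distance(
                clusters[keys[x]][1][0], clusters[keys[y]][1][0], k
            )

    def d(a, b):
        return dist[frozenset((a, b))]

    while len(clusters) > 1:
        keys = sorted(clusters)
        r = len(keys)
        if r == 2:
            pair = (keys[0], keys[1])
        else:
            R = {a: sum(d(a, b) for b in keys if b != a) for a in keys}
            pair, best_q = None, None
            for x in range(r):
                for y in range(x + 1, r):
                    a, b = keys[x], keys[y]
                    q = (r - 2) * d(a, b) - R[a] - R[b]
                    if best_q is None or q < best_q:
                        best_q, pair = q, (a, b)
        a, b = pair
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        new_a, new_b, _ = _align_profiles(rows_a, rows_b, kind, gap_open, gap_extend)
        u = tuple(sorted(a + b))
        clusters[u] = (ids_a + ids_b, new_a + new_b)
        for other in list(clusters):
            if other == u:
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((u, other))] = 0.5 * (da + db - d(a, b)) if len(keys) > 2 \
                else 0.5 * (da + db)
        dist.pop(frozenset((a, b)), None)

    (ids, rows), = clusters.values()
    order = {sid: i for i, (sid, _) in enumerate(seq_list)}
    merged = sorted(zip(ids, rows), key=lambda t: order[t[0]])
    return Alignment(
        ids=tuple(m[0] for m in merged),
        rows=tuple(m[1] for m in merged),
        kind=kind,
    )


# ---------------------------------------------------------------------------
# block cleaning
# ---------------------------------------------------------------------------

def clean_blocks(aln: Alignment, max_gap_frac: float = 0.5,
                 min_conserved_frac: float = 0.5, min_block: int = 5) -> Alignment:
    """Keep maximal runs (>= min_block) of gap-poor, conserved columns."""
    nrows = aln.n_rows
    good = []
    for j in range(aln.n_columns):
        col = aln.column(j)
        gaps = col.count(GAP)
        residues = [c for c in col if c != GAP]
        top = max((residues.count(c) for c in set(residues)), default=0)
        good.append(
            gaps / nrows <= max_gap_frac and top / nrows >= min_conserved_frac
        )
    keep: list[int] = []
    run: list[int] = []
    for j, ok in enumerate(good):
        if ok:
            run.append(j)
        else:
            if len(run) >= min_block:
                keep.extend(run)
            run = []
    if len(run) >= min_block:
        keep.extend(run)
    if not keep:
        raise BlockCleaningError("no blocks retained")
    rows = tuple("".join(r[j] for j in keep) for r in aln.rows)
    return Alignment(ids=aln.ids, rows=rows, kind=aln.kind)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distance_matrix(aln: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances with per-pair deletion of gapped sites.

    model "p": mismatch fraction; "poisson": -ln(1 - p) (errors on p = 1).
    """
    if model not in ("p", "poisson"):
        raise ValueError("model must be 'p' or 'poisson'")
    if aln.n_rows < 2:
        raise ValueError("need at least 2 rows")
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows]
    gap = ord(GAP)
    n = aln.n_rows
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (arrs[i] != gap) & (arrs[j] != gap)
            total = int(valid.sum())
            if total == 0:
                raise SaturatedDistanceError(
                    f"no shared ungapped sites between {aln.ids[i]} and {aln.ids[j]}"
                )
            p = float(((arrs[i] != arrs[j]) & valid).sum()) / total
            if model == "poisson":
                if p >= 1.0:
                    raise SaturatedDistanceError(
                        f"saturated distance between {aln.ids[i]} and {aln.ids[j]}"
                    )
                p = -_ln(1.0 - p)
            out[i, j] = out[j, i] = p
    return DistanceMatrix(labels=aln.ids, values=out)


# ---------------------------------------------------------------------------
# NJ / BioNJ
# ---------------------------------------------------------------------------

def nj_tree(D: DistanceMatrix, variant: str = "nj") -> dendropy.Tree:
    """Neighbor joining (or BioNJ) on a distance matrix; unrooted tree.

    Q-criterion pair selection with lexicographic tie-breaks; branch lengths
    from the standard formulas, negatives clamped to zero with the deficit
    moved to the sister branch.  BioNJ replaces the plain averaging of the
    distance reduction with the variance-weighted average (see module notes).
    """
    if variant not in ("nj", "bionj"):
        raise ValueError("variant must be 'nj' or 'bionj'")
    labels = list(D.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    tns = dendropy.TaxonNamespace(labels)
    nodes: dict[tuple, dendropy.Node] = {}
    for lbl in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lbl)
        nodes[(lbl,)] = node
    dist: dict[frozenset, float] = {}
    var: dict[frozenset, float] = {}
    keys = sorted(nodes)
    for x in range(n):
        for y in range(x + 1, n):
            a, b = keys[x], keys[y]
            val = D.get(a[0], b[0])
            dist[frozenset((a, b))] = val
            var[frozenset((a, b))] = val

    def d(a, b):
        return dist[frozenset((a, b))]

    def v(a, b):
        return var[frozenset((a, b))]

    active = set(nodes)
    while len(active) > 3:
        keys = sorted(active)
        r = len(keys)
        R = {a: sum(d(a, b) for b in keys if b != a) for a in keys}
        pair, best_q = None, None
        for x in range(r):
            for y in range(x + 1, r):
                a, b = keys[x], keys[y]
                q = (r - 2) * d(a, b) - R[a] - R[b]
                if best_q is None or q < best_q:
                    best_q, pair = q, (a, b)
        a, b = pair
        dab = d(a, b)
        la = 0.5 * dab + (R[a] - R[b]) / (2 * (r - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
            la = max(la, 0.0)
        if variant == "bionj" and v(a, b) > 0:
            lam = 0.5 + sum(
                v(b, c) - v(a, c) for c in keys if c not in (a, b)
            ) / (2 * (r - 2) * v(a, b))
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        u = tuple(sorted(a + b))
        parent = dendropy.Node()
        na, nb = nodes.pop(a), nodes.pop(b)
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = la
        nb.edge.length = lb
        nodes[u] = parent
        active.remove(a)
        active.remove(b)
        for c in list(active):
            duc = lam * (d(a, c) - la) + (1 - lam) * (d(b, c) - lb)
            dist[frozenset((u, c))] = max(duc, 0.0)
            var[frozenset((u, c))] = max(
                lam * v(a, c) + (1 - lam) * v(b, c) - lam * (1 - lam) * v(a, b),
                0.0,
            )
        active.add(u)

    tree = dendropy.Tree(taxon_namespace=tns)
    keys = sorted(active)
    if len(keys) == 1:
        tree.seed_node = nodes[keys[0]]
    elif len(keys) == 2:
        a, b = keys
        center = dendropy.Node()
        half = d(a, b) / 2
        for kk, ln in ((a, half), (b, half)):
            center.add_child(nodes[kk])
            nodes[kk].edge.length = ln
        tree.seed_node = center
    else:
        a, b, c = keys
        center = dendropy.Node()
        la = max(0.0, (d(a, b) + d(a, c) - d(b, c)) / 2)
        lb = max(0.0, (d(a, b) + d(b, c) - d(a, c)) / 2)
        lc = max(0.0, (d(a, c) + d(b, c) - d(a, b)) / 2)
        for kk, ln in ((a, la), (b, lb), (c, lc)):
            center.add_child(nodes[kk])
            nodes[kk].edge.length = ln
        tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# splits, bootstrap, collapse
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def tree_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions, each canonicalized to the side that does not
    contain the lexicographically smallest leaf."""
    all_leaves = leaf_labels(tree)
    anchor = min(all_leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def default_tree_builder(aln: Alignment) -> dendropy.Tree:
    """p-distance + BioNJ (robust under bootstrap resampling)."""
    return nj_tree(distance_matrix(aln, model="p"), variant="bionj")


def bootstrap_support(seqs, builder=None, n_reps: int = 100,
                      seed: int = 0) -> dendropy.Tree:
    """Column bootstrap: resample alignment columns with replacement, rebuild,
    and label each internal branch of the original tree with the percentage of
    replicates containing its bipartition.

    ``seqs`` may be an :class:`Alignment` (used as-is) or raw sequences (then
    aligned once with :func:`progressive_msa`; replicates resample the fixed
    alignment, they do not re-align).
    """
    if builder is None:
        builder = default_tree_builder
    aln = seqs if isinstance(seqs, Alignment) else progressive_msa(seqs)
    tree = builder(aln)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {s: 0 for s in tree_splits(tree)}
    ncol = aln.n_columns
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rows = tuple("".join(r[j] for j in idx) for r in aln.rows)
        try:
            rep_aln = Alignment(ids=aln.ids, rows=rows, kind=aln.kind)
            rep_tree = builder(rep_aln)
        except (ValueError, AlignmentError):
            continue  # degenerate resample (e.g. all-gap column)
        rep_splits = tree_splits(rep_tree)
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    all_leaves = leaf_labels(tree)
    anchor = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            pct = 100.0 * counts[side] / n_reps
            node.support = pct
            node.label = str(int(round(pct)))
    tree.bootstrap_supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return tree


def collapse_low_support(tree: dendropy.Tree, threshold: float = 40.0) -> dendropy.Tree:
    """Contract internal edges with support below ``threshold`` into polytomies.

    The contracted edge's length is added to each child edge; the leaf set is
    unchanged.  Edges without a support value are kept.
    """
    from .seq_io import node_support

    for node in list(tree.preorder_node_iter()):
        if node.parent_node is None or node.is_leaf():
            continue
        sup = node_support(node)
        if sup is None or sup >= threshold:
            continue
        parent = node.parent_node
        extra = node.edge.length or 0.0
        for child in list(node.child_nodes()):
            child.edge.length = (child.edge.length or 0.0) + extra
            node.remove_child(child)
            parent.add_child(child)
        parent.remove_child(node)
    return tree


def is_clade(tree: dendropy.Tree, labels) -> bool:
    """True if ``labels`` appear together on one side of some branch."""
    want = frozenset(labels)
    all_leaves = leaf_labels(tree)
    if want == all_leaves or len(want) == 1:
        return True
    anchor = min(all_leaves)
    canon = (all_leaves - want) if anchor in want else want
    return canon in tree_splits(tree) or len(canon) in (1, len(all_leaves) - 1)
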