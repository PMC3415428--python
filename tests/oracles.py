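"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an expected result by exhaustive enumeration or a
direct definitional computation, never sharing code with the implementation
it checks.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive global affine-gap alignment
# ---------------------------------------------------------------------------

def brute_force_align_score(a: str, b: str, subst, gap_open: float,
                            gap_extend: float) -> float:
    """Best global alignment score by enumerating every monotone path.

    A gap run of length L costs gap_open + gap_extend * L; the run state is
    carried explicitly so affine costs are charged exactly once per run.
    """
    best = [float("-inf")]
    na, nb = len(a), len(b)

    def rec(i, j, score, state):
        if i == na and j == nb:
            if score > best[0]:
                best[0] = score
            return
        if i < na and j < nb:
            rec(i + 1, j + 1, score + subst(a[i], b[j]), "M")
        if i < na:
            cost = gap_extend if state == "X" else gap_open + gap_extend
            rec(i + 1, j, score - cost, "X")
        if j < nb:
            cost = gap_extend if state == "Y" else gap_open + gap_extend
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, "M")
    return best[0]


# ---------------------------------------------------------------------------
# exhaustive per-period tandem repeat scan
# ---------------------------------------------------------------------------

def brute_force_repeat_scan(s: str, min_period: int, max_period: int,
                            min_identity: float) -> dict[int, int]:
    """Max copy number per period, by direct copy-vs-next-copy comparison.

    For each period p, a chain of c-1 consecutive "good" blocks (each block
    of p positions where s[i] == s[i+p] at >= min_identity of sites) is an
    array of c copies.  Returns {period: max copies (>= 1)}.
    """
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    n = len(s)
    out: dict[int, int] = {}
    for p in range(min_period, min(max_period, n // 2) + 1):
        m = (arr[:-p] == arr[p:]).astype(np.int64)
        cs = np.concatenate([[0], np.cumsum(m)])
        L = len(m)
        nblocks = L - p + 1
        if nblocks <= 0:
            out[p] = 1
            continue
        good = (cs[p:] - cs[:-p]) >= min_identity * p  # good[i]: block at i
        chain = np.zeros(nblocks, dtype=np.int64)
        for i in range(nblocks - 1, -1, -1):
            if good[i]:
                nxt = chain[i + p] if i + p < nblocks else 0
                chain[i] = 1 + nxt
        out[p] = int(chain.max()) + 1 if chain.size else 1
    return out


# ---------------------------------------------------------------------------
# exhaustive duplication-loss reconciliation
# ---------------------------------------------------------------------------

def _species_index(species_tree):
    parent, depth = {}, {}
    leaf = {}
    for node in species_tree.preorder_node_iter():
        p = node.parent_node
        parent[node] = p
        depth[node] = 0 if p is None else depth[p] + 1
        if node.is_leaf():
            leaf[node.taxon.label if node.taxon else node.label] = node
    return parent, depth, leaf


def brute_force_reconcile(gene_tree, species_tree, leaf_map):
    """Minimum duplications (and losses among min-duplication mappings) over
    every valid gene-to-species node mapping, by explicit enumeration."""
    parent, depth, leaf = _species_index(species_tree)

    def lca(x, y):
        while depth[x] > depth[y]:
            x = parent[x]
        while depth[y] > depth[x]:
            y = parent[y]
        while x is not y:
            x, y = parent[x], parent[y]
        return x

    def ancestors_or_self(node):
        out = []
        while node is not None:
            out.append(node)
            node = parent[node]
        return out

    def all_maps(gnode):
        if gnode.is_leaf():
            glabel = gnode.taxon.label if gnode.taxon else gnode.label
            yield {gnode: leaf[leaf_map[glabel]]}
            return
        c1, c2 = gnode.child_nodes()
        for m1 in all_maps(c1):
            for m2 in all_maps(c2):
                base = lca(m1[c1], m2[c2])
                for anc in ancestors_or_self(base):
                    m = dict(m1)
                    m.update(m2)
                    m[gnode] = anc
                    yield m

    def child_containing(snode, target):
        # which child subtree of snode contains target (None if target==snode)
        if target is snode:
            return None
        x = target
        while parent[x] is not snode:
            x = parent[x]
        return x

    def count_events(mapping):
        dups = losses = 0
        for v in mapping:
            if v.is_leaf():
                continue
            c1, c2 = v.child_nodes()
            mv, m1, m2 = mapping[v], mapping[c1], mapping[c2]
            s1 = child_containing(mv, m1)
            s2 = child_containing(mv, m2)
            dup = s1 is None or s2 is None or s1 is s2
            if dup:
                dups += 1
            for mc in (m1, m2):
                d = depth[mc] - depth[mv]
                if mc is mv:
                    continue
                losses += d if dup else d - 1
        return dups, losses

    best = None
    for mapping in all_maps(gene_tree.seed_node):
        dups, losses = count_events(mapping)
        if best is None or (dups, losses) < best:
            best = (dups, losses)
    return best


# ---------------------------------------------------------------------------
# random trees and protein mutation helpers
# ---------------------------------------------------------------------------

def random_binary_newick(rng, labels, min_bl=0.1, max_bl=1.0) -> str:
    """Random rooted binary topology with uniform branch lengths, as Newick."""
    subtrees = [f"{lbl}" for lbl in labels]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        la = rng.uniform(min_bl, max_bl)
        lb = rng.uniform(min_bl, max_bl)
        subtrees.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return subtrees[0] + ";"


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def mutate_protein(rng, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            choices = [a for a in AA20 if a != ch]
            out.append(choices[int(rng.integers(len(choices)))])
        else:
            out.append(ch)
    return "".join(out)


def random_protein(rng, length: int) -> str:
    return "".join(AA20[int(i)] for i in rng.integers(len(AA20), size=length))
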