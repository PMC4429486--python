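"""Independent brute-force oracles used to validate the implementations.

Each oracle enumerates exhaustively and shares no code path with the
module it checks.
"""

from __future__ import annotations

import itertools
import math

from dcltools.duplex import PenaltyScheme

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WEIGHT = {
    ("A", "T"): 2, ("T", "A"): 2, ("C", "G"): 2, ("G", "C"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


def brute_duplex_score(mirna: str, window: str, scheme: PenaltyScheme) -> float:
    """Minimum penalty over ALL global duplex alignments with bounded bulges.

    Recursion over (miRNA consumed, reversed-window consumed, bulges used),
    accumulating penalties path by path; no tables, no tie-breaks.
    """
    t = window[::-1]
    M, W = len(mirna), len(t)
    B = scheme.max_bulged_nt

    def pos_mult(p: int) -> float:
        lo, hi = scheme.core_range
        return scheme.core_multiplier if lo <= p <= hi else 1.0

    best = [math.inf]

    def rec(i: int, j: int, b: int, acc: float) -> None:
        if acc >= best[0]:
            return
        if i == M and j == W:
            best[0] = acc
            return
        if i < M and j < W:
            m, x = mirna[i], t[j]
            if _COMP[m] == x:
                pen = 0.0
            elif (m, x) in (("G", "T"), ("T", "G")):
                pen = scheme.gu_penalty * pos_mult(i + 1)
            else:
                pen = scheme.mismatch_penalty * pos_mult(i + 1)
            rec(i + 1, j + 1, b, acc + pen)
        if b < B:
            if i < M:
                rec(i + 1, j, b + 1,
                    acc + scheme.bulge_penalty_per_nt * pos_mult(i + 1))
            if j < W:
                rec(i, j + 1, b + 1,
                    acc + scheme.bulge_penalty_per_nt * pos_mult(max(i, 1)))

    rec(0, 0, 0, 0.0)
    return best[0]


def brute_max_pairing(seq: str, min_loop: int = 3) -> int:
    """Best total weight over all non-crossing pairings, by enumeration."""

    def rec(lo: int, hi: int) -> int:
        if hi - lo <= min_loop:
            return 0
        best = rec(lo + 1, hi)  # lo unpaired
        for k in range(lo + min_loop + 1, hi + 1):
            w = _WEIGHT.get((seq[lo], seq[k]), 0)
            if w:
                best = max(best, w + rec(lo + 1, k - 1) + rec(k + 1, hi))
        return best

    return rec(0, len(seq) - 1)


def brute_fitch_events(tree, tip_states: dict[str, str]) -> int:
    """Minimum state changes over all internal labelings of a dendropy tree."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = math.inf
    for combo in itertools.product(("absent", "present"), repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), combo))

        def state(node):
            if node.is_leaf():
                return tip_states[node.taxon.label]
            return assign[id(node)]

        events = 0
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                if state(child) != state(node):
                    events += 1
        best = min(best, events)
    return int(best)


def brute_pi(residues: str, net_charge, pka, step: float = 0.001) -> float:
    """pH grid scan minimizing |net charge|."""
    best_ph, best_abs = 0.0, math.inf
    ph = 0.0
    while ph <= 14.0:
        c = abs(net_charge(residues, ph, pka))
        if c < best_abs:
            best_abs, best_ph = c, ph
        ph += step
    return best_ph


def random_additive_matrix(ntips: int, rng):
    """Distance matrix of a random tree with random positive branch lengths.

    Built by repeated random joins; returns (matrix, None). Any such matrix
    is additive by construction, so NJ must recover it exactly.
    """
    import numpy as np

    nodes = [(i, {i}) for i in range(ntips)]
    D = np.zeros((ntips, ntips))
    dist_to = {i: {i: 0.0} for i in range(ntips)}
    nxt = ntips
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (a, ta), (b, tb) = nodes[i], nodes[j]
        la, lb = rng.uniform(0.05, 1.0, 2)
        for x in ta:
            for y in tb:
                D[x, y] = D[y, x] = dist_to[a][x] + la + lb + dist_to[b][y]
        dist_to[nxt] = {
            **{x: dist_to[a][x] + la for x in ta},
            **{y: dist_to[b][y] + lb for y in tb},
        }
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append((nxt, ta | tb))
        nxt += 1
    return D


def tree_path_lengths(tree) -> dict:
    """All tip-to-tip path lengths of a PhyloTree, by traversal."""
    import collections

    adj = collections.defaultdict(list)
    names = {}

    def build(node):
        if node.is_leaf():
            names[id(node)] = node.name
        for c, ln in node.children:
            adj[id(node)].append((id(c), ln))
            adj[id(c)].append((id(node), ln))
            build(c)

    build(tree.root)
    out = {}
    for src, sname in names.items():
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for tgt, tname in names.items():
            out[(sname, tname)] = dist[tgt]
    return out
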