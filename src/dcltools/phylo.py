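"""Protein-distance neighbor-joining trees with bootstrap support.

Distances are computed from a multiple protein alignment with pairwise
deletion of gapped columns, either as the raw mismatch fraction
(p-distance) or Poisson-corrected (-ln(1-p)). Trees are built by the
Saitou-Nei neighbor-joining agglomeration with deterministic lexicographic
tie-breaking; bootstrap support is the percentage of column-resampled
replicates containing each original bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

GAP_CHARS = set("-.")


@dataclass(frozen=True)
class MultipleAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MultipleAlignment":
        ids, rows, cur = [], [], []
        for line in Path(path).read_text().splitlines():
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                ids.append(line[1:].split()[0])
            elif line.strip():
                cur.append(line.strip().upper())
        if cur:
            rows.append("".join(cur))
        return cls(tuple(ids), tuple(rows))

    def subcolumns(self, cols: Sequence[int]) -> "MultipleAlignment":
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return MultipleAlignment(self.ids, rows)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_tsv(self) -> str:
        lines = ["\t".join(["#id"] + list(self.ids))]
        for i, name in enumerate(self.ids):
            lines.append(
                name + "\t" + "\t".join(f"{v:.6f}" for v in self.matrix[i])
            )
        return "\n".join(lines) + "\n"


def pairwise_distance(msa: MultipleAlignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise-deletion distances: p (mismatch fraction) or poisson."""
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    n = len(msa.ids)
    if n < 2:
        raise ValueError("need at least two rows")
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows]
    gaps = [np.isin(a, np.frombuffer(b"-.", dtype=np.uint8)) for a in arrs]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(gaps[i] | gaps[j])
            total = int(shared.sum())
            if total == 0:
                raise ValueError(
                    f"no shared ungapped columns between {msa.ids[i]!r} "
                    f"and {msa.ids[j]!r}"
                )
            p = float((arrs[i][shared] != arrs[j][shared]).sum()) / total
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("p-distance of 1.0 cannot be Poisson corrected")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(tuple(msa.ids), d)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class Node:
    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    root: Node
    model: str = "poisson"

    def tips(self) -> list[str]:
        return sorted(self.root.leaves())

    def newick(self, decimals: int = 6, with_support: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(
                f"{fmt(c)}:{ln:.{decimals}f}" for c, ln in node.children
            )
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized to the side away from the
        lexicographically first tip."""
        all_tips = frozenset(self.root.leaves())
        anchor = min(all_tips)
        splits: set[frozenset[str]] = set()

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_tips) - 1:
                side = below if anchor not in below else all_tips - below
                splits.add(side)
            return below

        for child, _ in self.root.children:
            walk(child)
        return splits

    def internal_nodes(self) -> list[Node]:
        out = []

        def walk(node: Node) -> None:
            if not node.is_leaf():
                out.append(node)
                for c, _ in node.children:
                    walk(c)

        walk(self.root)
        return out


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling edge. Join ties are broken by the lexicographically
    smallest (id, id) pair. The final three lineages are attached to a
    trifurcating root, giving a stable unrooted newick.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least three taxa")
    nodes: list[Node] = [Node(name=i) for i in dm.ids]
    labels: list[str] = list(dm.ids)  # lexicographic tie-break key per cluster
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[a, b] for b in active if b != a) for a in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                a, b = active[ai], active[bi]
                q = (m - 2) * d[a, b] - r[a] - r[b]
                key = tuple(sorted((labels[a], labels[b])))
                if best is None or (q, key) < (best[0], best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        la = 0.5 * d[a, b] + (r[a] - r[b]) / (2 * (m - 2))
        lb = d[a, b] - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = Node(children=[(nodes[a], la), (nodes[b], lb)])
        # grow the matrix by one row/col for the new cluster
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in active:
            if c in (a, b):
                continue
            d[k, c] = d[c, k] = 0.5 * (d[a, c] + d[b, c] - d[a, b])
        nodes.append(new)
        labels.append(min(labels[a], labels[b]))
        active = [c for c in active if c not in (a, b)] + [k]

    a, b, c = sorted(active, key=lambda x: labels[x])
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = Node(
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ]
    )
    return PhyloTree(root)


def bootstrap_support(
    msa: MultipleAlignment,
    n: int = 1000,
    seed: int = 0,
    model: str = "poisson",
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Support on each internal node is the percentage of ``n`` replicates
    whose NJ tree contains the same bipartition; seeded and reproducible.
    """
    tree = nj_tree(pairwise_distance(msa, model))
    tree.model = model
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n):
        cols = rng.integers(0, msa.ncol, size=msa.ncol)
        rep = msa.subcolumns(list(cols))
        try:
            rep_tree = nj_tree(pairwise_distance(rep, model))
        except ValueError:  # degenerate replicate (e.g. all-gap columns)
            continue
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_tips = frozenset(tree.root.leaves())
    anchor = min(all_tips)

    def annotate(node: Node) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c, _ in node.children))
        if 1 < len(below) < len(all_tips) - 1:
            side = below if anchor not in below else all_tips - below
            node.support = round(100.0 * counts[side] / n, 1)
        return below

    for child, _ in tree.root.children:
        annotate(child)
    return tree
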