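"""Neighbor-joining trees with bootstrap bipartition support.

The agglomeration is the classic Saitou–Nei procedure: minimize the
Q-criterion, join, derive branch lengths (negatives clamped to zero),
reduce the matrix.  Ties are broken by the smallest (row, column) index
pair in the current matrix order, which makes runs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for child, _bl in self.children:
            out.extend(child.leaves())
        return out


def pad_align(sequences: dict[str, str]) -> dict[str, str]:
    """Trivial gap-free alignment fallback: right-pad to equal length."""
    if not sequences:
        return {}
    width = max(len(s) for s in sequences.values())
    return {name: seq.ljust(width, "-") for name, seq in sequences.items()}


def p_distance_matrix(
    alignment: dict[str, str] | list[tuple[str, str]],
) -> tuple[list[str], np.ndarray]:
    """Pairwise proportion of differing sites over pairwise-ungapped columns."""
    items = list(alignment.items()) if isinstance(alignment, dict) else list(alignment)
    if len(items) < 3:
        raise ValueError("need >= 3 sequences")
    labels = [name for name, _ in items]
    seqs = [seq.upper() for _, seq in items]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned sequences differ in length")
    arr = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    gap = ord("-")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != gap) & (arr[j] != gap)
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}"
                )
            d[i, j] = d[j, i] = (arr[i][ok] != arr[j][ok]).sum() / total
    return labels, d


def nj_tree(labels: list[str], matrix: np.ndarray) -> TreeNode:
    """Unrooted NJ tree (returned with a trifurcating root node)."""
    D = np.asarray(matrix, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in labels]
    D = D.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties resolved by first (row, col) in scan order
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        D = D2

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max((d01 + d02 - d12) / 2.0, 0.0)
    l1 = max((d01 + d12 - d02) / 2.0, 0.0)
    l2 = max((d02 + d12 - d01) / 2.0, 0.0)
    return TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])


def tree_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix (for additivity checks)."""
    leaves = sorted(tree.leaves())
    index = {name: i for i, name in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def below(node: TreeNode) -> list[tuple[str, float]]:
        """Leaves under ``node`` with their distance from it."""
        if node.is_leaf:
            return [(node.name or "", 0.0)]
        groups = [
            [(leaf, dist + bl) for leaf, dist in below(child)]
            for child, bl in node.children
        ]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for la, da in groups[a]:
                    for lb, db in groups[b]:
                        i, j = index[la], index[lb]
                        d[i, j] = d[j, i] = da + db
        return [x for g in groups for x in g]

    below(tree)
    return leaves, d


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalized as the side not containing
    the alphabetically first leaf."""
    all_leaves = set(tree.leaves())
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> set[str]:
        if node.is_leaf:
            return {node.name or ""}
        mine: set[str] = set()
        for child, _bl in node.children:
            side = walk(child)
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(frozenset(side if ref not in side else all_leaves - side))
            mine |= side
        return mine

    walk(tree)
    return out


def bootstrap_support(
    alignment: dict[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
    tree: TreeNode | None = None,
) -> TreeNode:
    """Attach bootstrap percentages (column resampling) to the internal
    edges of the NJ tree of ``alignment``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels, d = p_distance_matrix(alignment)
    if tree is None:
        tree = nj_tree(labels, d)
    all_leaves = set(tree.leaves())
    ref = min(all_leaves)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(tree)}

    names = list(alignment)
    arr = np.array(
        [np.frombuffer(alignment[n].encode(), dtype=np.uint8) for n in names]
    )
    ncols = arr.shape[1]
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep = {n: arr[i, cols].tobytes().decode() for i, n in enumerate(names)}
        rl, rd = p_distance_matrix(rep)
        for bp in bipartitions(nj_tree(rl, rd)):
            if bp in counts:
                counts[bp] += 1

    def annotate(node: TreeNode) -> set[str]:
        if node.is_leaf:
            return {node.name or ""}
        mine: set[str] = set()
        for child, _bl in node.children:
            side = annotate(child)
            if 2 <= len(side) <= len(all_leaves) - 2:
                key = frozenset(side if ref not in side else all_leaves - side)
                child.support = 100.0 * counts.get(key, 0) / n_replicates
            mine |= side
        return mine

    annotate(tree)
    return tree


def to_newick(tree: TreeNode, with_support: bool = True) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name or ""
        inner = ",".join(
            f"{fmt(child)}:{bl:.6g}" for child, bl in node.children
        )
        label = ""
        if with_support and node.support is not None:
            label = f"{node.support:.4g}"
        return f"({inner}){label}"

    return fmt(tree) + ";"
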